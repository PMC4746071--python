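# Methods

This note documents the models, conventions, defaults and limitations of
the package. Everything quantitative stated here is computed by the test
suite or the example scripts; nothing is asserted beyond what the code
reproduces.

## The proportional-odds model and its orientation

All ordinal regressions use the cumulative-logit (proportional-odds, PO)
model with the orientation

    P(Y ≤ i | x) = logistic(Z_i − x·β),  i = 1..K−1,

for the K=4-level self-reported health outcome (1 = poor … 4 = very good).
The published coefficient signs are only interpretable under a definite
orientation; under this one a *negative* coefficient is harmful, the odds
ratio of reporting *lower* SRH is exp(−β), and the bundled published model
yields sensible predictions (a healthy 25-year-old woman has
P(poor) ≈ 0.0006 and expected SRH ≈ 3.53, reproduced by hand in the tests).
The convention is stamped into every serialized model as
`convention_note`, so model files are self-describing.

Category probabilities are consecutive differences of the cumulative
probabilities; the expected outcome is E[Y] = Σ k·P(Y=k), which for K
categories equals K minus the sum of the K−1 cumulative probabilities —
the "total of the cumulative proportions" identity used when predicting an
average SRH per subject.

## Fitting

Maximum likelihood is delegated to statsmodels' `OrderedModel`
(logit link), whose parameterization matches the package convention and
enforces threshold monotonicity internally via log-increments. A BFGS fit
(gradient tolerance 1e-8) is followed by a Newton-CG polish kept only when
it improves the log-likelihood; this makes the K=2 special case agree with
an ordinary binary logit to ~1e-9, which the tests check as an external
equivalence oracle alongside a brute-force local-optimality check (1,000
random perturbations of norm 0.1 around the optimum).

Per-covariate uncertainty uses Wald standard errors and 95% CIs from the
observed information matrix — the default of the software the original
analysis names, and the only interval type whose published presentation is
unambiguous. The likelihood-ratio test is against the closed-form
intercept-only multinomial likelihood, and Nagelkerke's pseudo-R² is
(1−(L0/L1)^(2/n)) / (1−L0^(2/n)) with n the complete-case count of the
fitted model.

Degenerate designs fail fast with the offending covariate named: constant
columns, rank-deficient design matrices (detected by QR pivoting),
outcomes with fewer than three observed categories (K=2 requires the
explicit `allow_binary` flag), and non-convergence (suspected separation).

## The PO-assumption diagnostic

`po_assumption_check` fits a separate binary logit of 1{Y≤i} at each
cutpoint and reports each covariate's OR across cutpoints plus the max/min
ratio, a violation indicator without a formal test statistic. Cutpoints
with fewer than 10 subjects on either side are skipped with a warning.
Partial proportional-odds models are deliberately not implemented; for a
covariate failing the check the documented recommendation is to report the
middle-threshold OR as the representative (median) value. Note the check
is a *conditional* statement: a covariate can satisfy PO jointly with the
full covariate set yet show drifting per-cutpoint ORs when fitted
marginally with covariates omitted, so the diagnostic should be run on the
same specification as the model it audits.

## Index derivation

The stepwise families mirror the published design: unadjusted
single-variable models; a base model of all conditions jointly; the base
model plus the 4-level mental-distress category (reference "no symptoms");
and the full contextual model adding 10-year age bands (reference 25–29)
and sex (female = 0). Conditions asked only of participants older than 70
(Parkinson's disease, arthritis, rheumatoid arthritis, urinary
incontinence, glaucoma, cataract) are fitted in a separate full model
restricted to the over-70 subcohort, and for younger subjects their status
is *missing*, never absent. Each family is fitted on its own complete-case
subset (listwise deletion).

Weights apply the published rule exactly as printed: conditions with
full-model OR ≤ 1.2 are excluded (boundary inclusive) and the rest get
weight = OR rounded half-up to the nearest natural number. Half-up is the
package's tie rule: every published OR→weight pair is consistent with
nearest-integer rounding and none sits at .5, so the tie policy was open;
half-up keeps the OR→weight map monotone. A per-condition override exists
because the published table itself contains one boundary exception:
hypersensitivity is listed with weight 1 although its printed OR is
exactly 1.20 (its unrounded OR presumably exceeded the threshold). The
bundled published table ships verbatim with that entry flagged
`override`; re-deriving from the printed ORs without the override excludes
it, and the tests document both facts.

Because weight assignment is a step function of the OR, exact recovery of
a generative weight table at finite n cannot be expected for conditions
whose true OR lies close to the 1.2 exclusion threshold or a .5 rounding
point, nor for very rare conditions (a handful of cases): sampling error
moves them one step. The recovery test therefore requires ≥90% exact
agreement away from boundaries (margin 0.1 on the OR scale, prevalence
≥1%) and never more than one step of disagreement overall.

## Scoring and the Charlson comparator

The HII of a subject is the sum of table weights over present conditions;
missing condition statuses score as absent (logged), since validation
needs a score for every subject. Groups are Not ill (0), Mildly ill (1–2),
Moderately ill (3–5), Seriously ill (≥6).

The original analysis reports Charlson correlations without printing its
condition-to-Charlson mapping, so the comparator's default map is the
package's own and fully configurable: myocardial infarction,
cerebrovascular stroke, diabetes, the two ulcer items, the two
chronic-pulmonary items, rheumatoid arthritis and liver disease at weight
1, cancer at weight 2, with category-level deduplication (two pulmonary
diagnoses count once, as do the two ulcer items — classic Charlson has a
single ulcer-disease category). The comparator only needs to reproduce the
qualitative full-vs-ill-only contrast, which it does on synthetic data.

## Prediction and validation

The prediction model regresses SRH on the continuous HII score, the
continuous 1–4 mental-distress score, age in years and sex — the full
contextual model with the specific conditions replaced by the index. Age
and mental distress are continuous here (unlike the banded derivation
models) because the published model prints a single coefficient per
variable. Prediction never reads the observed SRH column, so the same code
path serves external validation cohorts; the headline prediction is the
expected SRH, with the modal category also reported.

Validation statistics are two-sided throughout and use pairwise-complete
filtering with counts reported:

* **Spearman rho** with average ranks (scipy); the p-value is the
  exhaustive permutation tail for n ≤ 10 and the t approximation
  otherwise.
* **Wilcoxon signed rank** with zero differences dropped (not Pratt —
  matching the default of the software named by the original analysis)
  and tied absolute differences average-ranked. For n ≤ 25 the two-sided
  p is exact, from the tie-aware null distribution built by a
  generating-function convolution over doubled ranks; above that, the
  tie-corrected normal approximation. The z statistic is always the
  normal-approximation one, as that is what gets reported in practice.
* **Ill-only contrast**: Spearman of each index with SRH on the full
  sample and on the subsample that index itself scores > 0, with a
  qualitative strengthened/attenuated direction summary.
* **Descriptives**: per-level counts, mean and SD of SRH with
  Mann-Whitney (binary splits) or Kruskal-Wallis (multi-level) contrasts.

## The synthetic-cohort generator

The generator emulates the reference survey's structure with its printed
marginals as defaults: decade age-band probabilities from the printed
counts (the bands sum to 26,723 against a stated population of 26,684; the
probabilities are normalized and the 39-subject discrepancy is the
source's); P(male) = 12,661/26,684 ≈ 0.4745; condition prevalences =
printed count/26,684, with the six over-70 items against the over-70 model
denominator of 1,094 and generated only for subjects older than 70;
mental-distress category probabilities (2061, 15751, 4964, 1762)/24,538,
with ~8% joint missingness on the mental-health items mirroring their
smaller printed denominator. The continuous mental score is drawn per
category from truncated normals with means (1.05, 1.45, 1.95, 2.50) and
SDs (0.05, 0.20, 0.12, 0.30) on the 1–4 scale — chosen once so the
published 2.15 cutoff separates the top ("significant symptoms") category
and the population mean lands near 1.5; the tests verify both properties.

SRH is sampled from the published prediction model applied to the
subject's true HII by default; a per-condition mode (one log-OR per
condition plus mental-category, age-band and sex terms) exists for
end-to-end derivation testing. Conditions are sampled conditionally
independent given age; an optional shared-frailty knob (a per-subject
latent normal factor added to every condition's logit) induces
disease-disease correlation and reproduces the unadjusted-vs-base OR
attenuation that real comorbidity data show. Age trends on prevalence are
off by default (so configured marginals are exact by construction) and
available per condition as a log-OR per decade.

What the generator does **not** emulate: the real correlation structure
between specific diseases (unpublished), reporting/recall error in
self-reported diagnoses, informative missingness, and longitudinal waves.
Passing tests therefore demonstrate internal consistency of the method
under its own assumptions, not agreement with the restricted source data;
the sample-dependent published statistics (e.g. the full-sample Spearman
of −0.360) are covered by sign and direction properties only.

## Problem sizes and determinism

Simulation-based checks use cohorts of 20,000 subjects (coefficient
recovery, weight recovery, null-effect recovery, PO diagnostics) and 100
replicate cohorts of 20,000 for the calibration property — sizes at which
the Monte-Carlo error is comfortably below every tolerance asserted while
keeping the whole suite around two minutes on one core. All stochastic
steps run off a single integer seed through one `numpy` Generator, so
cohorts, fits and reports are bit-reproducible; a fixed-seed joint
CI-coverage check (all four coefficients inside their 95% CIs) is by
construction a ~81%-probability event per seed, and the suite runs it at
one pre-registered seed.

## Known limitations

* Partial proportional odds is documented but not fitted; survey weights,
  probit/cloglog links and random effects are out of scope.
* The exclusion threshold acts on rounded printed ORs when re-deriving
  from published tables; with full-precision ORs the single boundary case
  (hypersensitivity) would not need its override.
* The Charlson map is a survey-restricted approximation of the classic
  index, not an ICD-based implementation.
* Scores treat missing condition status as absent, which biases the index
  downward under heavy item non-response.
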