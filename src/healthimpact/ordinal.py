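"""Proportional-odds (cumulative-logit) regression for ordinal outcomes.

Orientation
-----------
All models in this package use the convention

    P(Y <= i | x) = logistic(Z_i - x.beta),   i = 1..K-1,

with strictly increasing thresholds ``Z_i``. Under it a *negative*
coefficient is harmful (it raises the probability of reporting lower
self-reported health), and the odds ratio of scoring at lower levels of the
outcome is ``exp(-beta)``. The convention is stamped into every
:class:`OrdinalModel` as ``convention_note`` so serialized models are
self-describing.

Maximum-likelihood fitting is delegated to
:class:`statsmodels.miscmodels.ordinal_model.OrderedModel`, whose native
parameterization matches the convention above (thresholds are internally
expressed as a first cutpoint plus log-increments, which enforces
monotonicity). Likelihood-ratio tests and the Nagelkerke pseudo-R-squared
are computed here against the closed-form intercept-only likelihood.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .cohort import CohortTable, SubjectRecord

logger = logging.getLogger(__name__)

CONVENTION_NOTE = (
    "Cumulative probabilities follow P(Y<=i | x) = logistic(Z_i - x.beta). "
    "Negative coefficients are harmful (raise the probability of lower "
    "outcome categories); the odds ratio of scoring at lower levels is "
    "exp(-beta)."
)


class ConvergenceError(RuntimeError):
    """Raised when the PO likelihood cannot be maximized (e.g. separation)."""


@dataclass(frozen=True)
class Categorical:
    """Categorical covariate: expanded to dummies against a reference level."""

    column: str
    reference: object

    def dummy_name(self, level) -> str:
        return f"{self.column}[{level}]"


CovariateSpec = Sequence[Union[str, Categorical]]


@dataclass
class OrdinalModel:
    """A fitted or published proportional-odds model.

    ``thresholds`` are the cutpoints Z_1 < ... < Z_{K-1}; ``coefficients``
    maps covariate name to the signed beta of the convention above.
    """

    thresholds: np.ndarray
    coefficients: dict
    covariate_spec: list = field(default_factory=list)
    convention_note: str = CONVENTION_NOTE

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1 or len(self.thresholds) < 1:
            raise ValueError("thresholds must be a non-empty 1-d vector")
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.covariate_spec:
            names = [
                c["name"] if isinstance(c, Mapping) else str(c)
                for c in self.covariate_spec
            ]
            if set(names) != set(self.coefficients):
                raise ValueError("covariate_spec names must match coefficients")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    @property
    def covariate_names(self) -> tuple:
        return tuple(self.coefficients)

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        return {
            "thresholds": [float(z) for z in self.thresholds],
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "covariate_spec": list(self.covariate_spec),
            "convention_note": self.convention_note,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "OrdinalModel":
        return cls(
            thresholds=np.asarray(doc["thresholds"], dtype=float),
            coefficients=dict(doc["coefficients"]),
            covariate_spec=list(doc.get("covariate_spec", [])),
            convention_note=doc.get("convention_note", CONVENTION_NOTE),
        )

    def save(self, path) -> None:
        path = str(path)
        doc = self.to_dict()
        with open(path, "w", encoding="utf-8") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(doc, fh, sort_keys=False)
            else:
                json.dump(doc, fh, indent=2)

    @classmethod
    def load(cls, path) -> "OrdinalModel":
        with open(str(path), encoding="utf-8") as fh:
            doc = (
                yaml.safe_load(fh)
                if str(path).endswith((".yaml", ".yml"))
                else json.load(fh)
            )
        return cls.from_dict(doc)


@dataclass
class FitReport:
    """Fit summary for a PO model: estimates, Wald CIs and fit statistics."""

    model: OrdinalModel
    log_likelihood: float
    lr_chi2: float
    lr_df: int
    lr_p: float
    nagelkerke_r2: float
    n_used: int
    se: dict
    ci95: dict


# ------------------------------------------------------------------ design


def _resolve_df(cohort) -> pd.DataFrame:
    return cohort.df if isinstance(cohort, CohortTable) else cohort


def build_design(
    df: pd.DataFrame, covariates: CovariateSpec
) -> tuple[pd.DataFrame, list]:
    """Expand a covariate spec into a numeric design frame.

    Plain strings are used as-is; :class:`Categorical` entries become 0/1
    dummies for every observed level except the reference.
    """
    cols = {}
    spec_out = []
    for cov in covariates:
        if isinstance(cov, Categorical):
            if cov.column not in df.columns:
                raise ValueError(f"covariate column not in cohort: '{cov.column}'")
            levels = sorted(pd.unique(df[cov.column].dropna()))
            if cov.reference not in levels:
                raise ValueError(
                    f"reference level {cov.reference!r} not observed for "
                    f"'{cov.column}'"
                )
            for lev in levels:
                if lev == cov.reference:
                    continue
                name = cov.dummy_name(lev)
                cols[name] = (df[cov.column] == lev).astype(float).where(
                    df[cov.column].notna()
                )
                spec_out.append(
                    {
                        "name": name,
                        "kind": "dummy",
                        "source": cov.column,
                        "level": lev,
                        "reference": cov.reference,
                    }
                )
        else:
            if cov not in df.columns:
                raise ValueError(f"covariate column not in cohort: '{cov}'")
            cols[str(cov)] = pd.to_numeric(df[cov], errors="coerce")
            spec_out.append({"name": str(cov), "kind": "continuous"})
    X = pd.DataFrame(cols, index=df.index)
    return X, spec_out


def _check_design(X: pd.DataFrame) -> None:
    for name in X.columns:
        if X[name].nunique(dropna=True) < 2:
            raise ValueError(f"covariate '{name}' is constant (inestimable)")
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr - arr.mean(axis=0)) < arr.shape[1]:
        # name one column involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(arr - arr.mean(axis=0))
        bad = X.columns[int(np.argmin(np.abs(np.diag(r))))]
        raise ValueError(f"design matrix not full rank (check covariate '{bad}')")


def _intercept_only_ll(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(np.sum(counts * np.log(p)))


def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2: (1-(L0/L1)^(2/n)) / (1-L0^(2/n))."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_r2) if max_r2 > 0 else 0.0


def fit_po(
    cohort,
    outcome: str,
    covariates: CovariateSpec,
    allow_binary: bool = False,
) -> FitReport:
    """Maximum-likelihood proportional-odds fit of ``outcome`` on covariates.

    Listwise deletion on the outcome and all covariate columns. The returned
    report carries the fitted :class:`OrdinalModel`, Wald standard errors
    and 95% CIs per covariate, the log-likelihood, the LR test against the
    intercept-only model, and the Nagelkerke pseudo-R-squared.
    """
    df = _resolve_df(cohort)
    if outcome not in df.columns:
        raise ValueError(f"outcome column not in cohort: '{outcome}'")
    X_all, spec = build_design(df, covariates)
    keep = df[outcome].notna() & X_all.notna().all(axis=1)
    y = df.loc[keep, outcome].to_numpy(dtype=float)
    X = X_all.loc[keep]
    n = len(y)
    n_cats = len(np.unique(y))
    if n_cats < 2 or (n_cats < 3 and not allow_binary):
        raise ValueError(
            f"outcome '{outcome}' has {n_cats} observed categories; "
            "use a binary logit for 2-category outcomes"
        )
    _check_design(X)

    mod = OrderedModel(y, X, distr="logit")
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        res = mod.fit(method="bfgs", maxiter=500, gtol=1e-8, disp=False)
        if res.mle_retvals.get("converged", False):
            # Newton polish tightens the optimum beyond BFGS's gradient tol;
            # keep it only when it improves on an already-converged fit
            try:
                import warnings

                with warnings.catch_warnings():
                    # the polish may stop on maxiter; we keep it only if it
                    # improves the likelihood, so its own warning is noise
                    warnings.simplefilter("ignore")
                    polished = mod.fit(
                        method="ncg", start_params=res.params, maxiter=50,
                        avextol=1e-12, disp=False,
                    )
                if polished.llf >= res.llf:
                    polished.mle_retvals["converged"] = True
                    res = polished
            except Exception:  # keep the BFGS solution
                pass
        else:
            res = mod.fit(method="ncg", maxiter=300, avextol=1e-10, disp=False)
    if not res.mle_retvals.get("converged", False):
        k = X.shape[1]
        grad = np.abs(mod.score(res.params)[:k])
        worst = X.columns[int(np.argmax(grad))]
        raise ConvergenceError(
            f"PO fit did not converge (suspect covariate '{worst}'; "
            "possible separation)"
        )

    k = X.shape[1]
    beta = np.asarray(res.params)[:k]
    thresholds = mod.transform_threshold_params(np.asarray(res.params))[1:-1]
    se = np.asarray(res.bse)[:k]
    ci = np.asarray(res.conf_int())[:k]
    names = list(X.columns)

    ll1 = float(res.llf)
    ll0 = _intercept_only_ll(y)
    lr = 2.0 * (ll1 - ll0)
    model = OrdinalModel(
        thresholds=np.asarray(thresholds, dtype=float),
        coefficients=dict(zip(names, beta.tolist())),
        covariate_spec=spec,
    )
    return FitReport(
        model=model,
        log_likelihood=ll1,
        lr_chi2=float(lr),
        lr_df=k,
        lr_p=float(chi2.sf(lr, k)),
        nagelkerke_r2=nagelkerke_r2(ll1, ll0, n),
        n_used=n,
        se=dict(zip(names, se.tolist())),
        ci95={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci)},
    )


# ------------------------------------------------------------------ predict


_RECORD_ATTRS = {
    "sex": "sex",
    "age": "age_years",
    "age_years": "age_years",
    "mhi": "mhi_score",
    "mhi_score": "mhi_score",
    "mhi_category": "mhi_category",
    "srh": "srh",
}


def _covariate_values(model: OrdinalModel, record) -> np.ndarray:
    if isinstance(record, SubjectRecord):
        vals = []
        for name in model.covariate_names:
            if name in _RECORD_ATTRS:
                v = getattr(record, _RECORD_ATTRS[name])
            elif name in record.conditions:
                c = record.conditions[name]
                v = None if c is None else float(c)
            else:
                v = None
            if v is None:
                raise ValueError(f"missing covariate '{name}' on record")
            vals.append(float(v))
        return np.asarray(vals)
    vals = []
    for name in model.covariate_names:
        if name not in record:
            raise ValueError(f"missing covariate '{name}'")
        v = record[name]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing covariate '{name}'")
        vals.append(float(v))
    return np.asarray(vals)


def cumulative_probs(model: OrdinalModel, xb: np.ndarray) -> np.ndarray:
    """P(Y<=i) for each threshold, given linear predictor value(s) x.beta."""
    xb = np.asarray(xb, dtype=float)
    return expit(model.thresholds - xb[..., None])


def predict_category_probs(model: OrdinalModel, record) -> np.ndarray:
    """Per-category probabilities (P(Y=1), ..., P(Y=K)) for one subject.

    ``record`` is a mapping of covariate name to value or a
    :class:`SubjectRecord`. P(Y=k) is the difference of consecutive
    cumulative probabilities.
    """
    x = _covariate_values(model, record)
    beta = np.asarray([model.coefficients[n] for n in model.covariate_names])
    cum = cumulative_probs(model, float(x @ beta))
    cum_full = np.concatenate(([0.0], cum, [1.0]))
    return np.diff(cum_full)


def expected_ordinal(model: OrdinalModel, record) -> float:
    """E[Y] = sum_k k*P(Y=k); equivalently K minus the summed cumulative
    probabilities (the "total of the cumulative proportions" reading)."""
    probs = predict_category_probs(model, record)
    return float(np.arange(1, len(probs) + 1) @ probs)


def odds_ratios(report: FitReport) -> dict:
    """Odds ratios of scoring at *lower* outcome levels, with 95% CIs.

    OR = exp(-beta) under the package convention, so a harmful covariate has
    OR > 1. CI endpoints are the exponentiated (negated, swapped) Wald
    limits.
    """
    out = {}
    for name, beta in report.model.coefficients.items():
        lo, hi = report.ci95[name]
        out[name] = {
            "or": float(np.exp(-beta)),
            "ci95": (float(np.exp(-hi)), float(np.exp(-lo))),
        }
    return out


# ------------------------------------------------------ PO-assumption check


@dataclass
class PoCheckResult:
    """Per-threshold ORs from separate binary logits, plus a max/min OR
    ratio per covariate as a proportional-odds-violation indicator."""

    per_threshold: pd.DataFrame  # rows: covariates, columns: thresholds
    or_ratio: dict  # covariate -> max/min OR across thresholds
    skipped_thresholds: list


def po_assumption_check(
    cohort,
    outcome: str,
    covariates: CovariateSpec,
    min_events: int = 10,
) -> PoCheckResult:
    """Fit a separate binary logit of 1{Y<=i} at each cutpoint.

    Under proportional odds every covariate's OR is constant across
    cutpoints, so the max/min ratio per covariate is ~1; large ratios flag a
    violation. Cutpoints leaving fewer than ``min_events`` subjects on
    either side are skipped with a warning. No formal test statistic is
    computed.
    """
    df = _resolve_df(cohort)
    if outcome not in df.columns:
        raise ValueError(f"outcome column not in cohort: '{outcome}'")
    X_all, _ = build_design(df, covariates)
    keep = df[outcome].notna() & X_all.notna().all(axis=1)
    y = df.loc[keep, outcome].to_numpy(dtype=float)
    X = X_all.loc[keep]
    cats = np.unique(y)
    if len(cats) < 3:
        raise ValueError("outcome must have >=3 observed categories")
    _check_design(X)

    ors = {}
    skipped = []
    for cut in cats[:-1]:
        event = (y <= cut).astype(float)
        n_event = int(event.sum())
        if min(n_event, len(event) - n_event) < min_events:
            logger.warning(
                "cutpoint Y<=%g skipped: only %d events", cut, n_event
            )
            skipped.append(float(cut))
            continue
        logit = sm.Logit(event, sm.add_constant(X, has_constant="add"))
        res = logit.fit(disp=0, maxiter=200)
        # event = lower outcome, so the OR of lower SRH is exp(+coef)
        ors[f"Y<={cut:g}"] = np.exp(np.asarray(res.params)[1:])
    if not ors:
        raise ValueError("no cutpoint had enough events for a binary logit")
    table = pd.DataFrame(ors, index=list(X.columns))
    ratio = (table.max(axis=1) / table.min(axis=1)).to_dict()
    return PoCheckResult(
        per_threshold=table, or_ratio=ratio, skipped_thresholds=skipped
    )
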