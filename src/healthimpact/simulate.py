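"""Synthetic survey cohorts with known generative truth.

The generator emulates the structure of a Tromso-style general-population
health survey: decade age bands, sex, ~30 self-reported conditions (six
asked only of the over-70s), a 4-level mental-distress category with a
continuous 1-4 mean score, and a 4-level self-reported health outcome
sampled from a proportional-odds truth model.

Two generative modes for SRH:

* **index mode** (default): the linear predictor uses the subject's true
  HII score (computed with a supplied weight table), continuous
  mental-distress score, age and sex — the published prediction model is
  the default truth.
* **per-condition mode**: the linear predictor carries one log-OR per
  condition plus mental-health-category, age-band and sex terms, matching
  the specification of the full contextual derivation model; used to test
  weight recovery end-to-end.

Conditions are sampled conditionally independent given age by default; a
shared-frailty knob (a per-subject latent normal factor added to every
condition's logit) induces disease-disease correlation to exercise the
unadjusted-vs-base OR attenuation that real comorbidity data show.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import CohortTable, ConditionCatalog, default_catalog
from .derivation import WeightTable, published_weights
from .ordinal import OrdinalModel
from .prediction import published_model

# --------------------------------------------------------------- config


@dataclass(frozen=True)
class AgeBand:
    lo: float
    hi: float  # inclusive upper age
    prob: float


@dataclass(frozen=True)
class ConditionSpec:
    baseline_prevalence: float
    age_log_or_per_decade: float = 0.0
    over70_only: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")


@dataclass(frozen=True)
class PerConditionTruth:
    """Per-condition generative SRH model (full-contextual-style)."""

    thresholds: Sequence[float]
    condition_log_ors: Mapping[str, float]  # log OR of lower SRH (>0 harmful)
    mhi_category_log_ors: Sequence[float] = (0.0, 1.09, 2.04, 3.03)  # level 1 ref
    age_band_log_ors: Sequence[float] = ()  # per band, first is reference
    sex_log_or: float = 0.0


@dataclass
class GeneratorConfig:
    """Full description of a synthetic cohort's data-generating process."""

    n: int
    seed: int
    age_bands: Sequence[AgeBand]
    sex_prob_male: float
    condition_specs: Mapping[str, ConditionSpec]
    mhi_category_probs: Sequence[float]
    mhi_score_means: Sequence[float] = (1.05, 1.45, 1.95, 2.50)
    mhi_score_sds: Sequence[float] = (0.05, 0.20, 0.12, 0.30)
    truth_model: Optional[OrdinalModel] = None
    weight_table: Optional[WeightTable] = None
    condition_truth: Optional[PerConditionTruth] = None
    missingness: Mapping[str, float] = field(default_factory=dict)
    frailty_sd: float = 0.0
    catalog: Optional[ConditionCatalog] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        probs = np.asarray([b.prob for b in self.age_bands], dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError("age band probabilities must be non-negative and sum to 1")
        mp = np.asarray(self.mhi_category_probs, dtype=float)
        if len(mp) != 4 or np.any(mp < 0) or not np.isclose(mp.sum(), 1.0, atol=1e-6):
            raise ValueError("mhi_category_probs must be 4 non-negative values summing to 1")
        if not 0.0 <= self.sex_prob_male <= 1.0:
            raise ValueError("sex_prob_male must be in [0, 1]")
        if self.condition_truth is None and (
            self.truth_model is None or self.weight_table is None
        ):
            raise ValueError(
                "either condition_truth or (truth_model and weight_table) required"
            )


# ------------------------------------------------------- default config

# printed marginal counts of the reference survey (denominator 26,684;
# over-70 items against the over-70 complete-case denominator 1,094)
_REF_N = 26_684
_REF_N_OVER70 = 1_094
_AGE_BAND_COUNTS = (
    (25, 29, 3046),
    (30, 39, 6769),
    (40, 49, 6644),
    (50, 59, 4413),
    (60, 69, 3099),
    (70, 79, 2145),
    (80, 97, 607),
)
_MALE_COUNT = 12_661
_MHI_CATEGORY_COUNTS = (2061, 15751, 4964, 1762)  # sum 24,538 (< 26,684)
_CONDITION_COUNTS = {
    "angina": 1097,
    "myocardial_infarction": 758,
    "cerebrovascular_stroke": 414,
    "asthma": 1876,
    "chronic_bronchitis": 1460,
    "epilepsy": 284,
    "migraine": 3280,
    "thyroid": 788,
    "diabetes": 482,
    "kidney_stone": 1113,
    "liver_disease": 393,
    "ventricular_ulcer": 1026,
    "duodenal_ulcer": 953,
    "cancer_survivor": 790,
    "psoriasis": 1636,
    "atopic_eczema": 2325,
    "hand_eczema": 3450,
    "pollen_allergies": 2851,
    "osteoporosis": 350,
    "food_allergies": 1769,
    "hypersensitivity": 3184,
    "fibromyalgia": 1872,
}
_OVER70_CONDITION_COUNTS = {
    "parkinsons_disease": 20,
    "arthritis": 730,
    "rheumatoid_arthritis": 162,
    "urinary_incontinence": 409,
    "glaucoma": 141,
    "cataract": 421,
}


def default_tromso4_config(n: int = _REF_N, seed: int = 0) -> GeneratorConfig:
    """Generator config matching the reference survey's printed marginals.

    Condition prevalences are marginal count / 26,684 (over-70 items use
    the over-70 model denominator 1,094); the male fraction is
    12,661/26,684 (~0.4745); mental-distress category probabilities follow
    the printed counts, with ~8% joint missingness on the mental-health
    items mirroring their smaller denominator. SRH is generated from the
    published prediction model applied to the published weight table.
    """
    total = sum(c for *_, c in _AGE_BAND_COUNTS)
    bands = tuple(
        AgeBand(lo, hi, c / total) for lo, hi, c in _AGE_BAND_COUNTS
    )
    specs = {
        cid: ConditionSpec(cnt / _REF_N) for cid, cnt in _CONDITION_COUNTS.items()
    }
    specs.update(
        {
            cid: ConditionSpec(cnt / _REF_N_OVER70, over70_only=True)
            for cid, cnt in _OVER70_CONDITION_COUNTS.items()
        }
    )
    mhi_total = sum(_MHI_CATEGORY_COUNTS)
    return GeneratorConfig(
        n=n,
        seed=seed,
        age_bands=bands,
        sex_prob_male=_MALE_COUNT / _REF_N,
        condition_specs=specs,
        mhi_category_probs=tuple(c / mhi_total for c in _MHI_CATEGORY_COUNTS),
        truth_model=published_model(),
        weight_table=published_weights(),
        missingness={"mhi": 1.0 - mhi_total / _REF_N},
        catalog=default_catalog(),
    )


# ------------------------------------------------------------- generation


def _sample_conditions(rng, cfg, ages, frailty) -> dict:
    cols = {}
    for cid, spec in cfg.condition_specs.items():
        eta = np.full(len(ages), logit(spec.baseline_prevalence))
        if spec.age_log_or_per_decade:
            centered = (ages - np.mean(ages)) / 10.0
            eta = eta + spec.age_log_or_per_decade * centered
        eta = eta + frailty
        present = (rng.random(len(ages)) < expit(eta)).astype(float)
        if spec.over70_only:
            present = np.where(ages > 70, present, np.nan)
        cols[cid] = present
    return cols


def _linear_predictor(cfg, df, band_idx) -> np.ndarray:
    """x.beta of the SRH truth model (negative = worse health)."""
    if cfg.condition_truth is not None:
        t = cfg.condition_truth
        eta = np.zeros(len(df))
        for cid, log_or in t.condition_log_ors.items():
            present = np.nan_to_num(df[cid].to_numpy(), nan=0.0)
            eta -= log_or * present  # harmful log-OR enters negatively
        mhi_terms = np.asarray(t.mhi_category_log_ors, dtype=float)
        eta -= mhi_terms[df["mhi_category"].to_numpy(dtype=int) - 1]
        if len(t.age_band_log_ors):
            eta -= np.asarray(t.age_band_log_ors, dtype=float)[band_idx]
        eta -= t.sex_log_or * df["sex"].to_numpy()
        return eta
    model = cfg.truth_model
    from .scoring import cohort_hii  # local to avoid cycle at import time

    values = {
        "hii": None,  # filled below
        "mhi": df["mhi_score"].to_numpy(),
        "age": df["age"].to_numpy(),
        "sex": df["sex"].to_numpy(),
    }
    eta = np.zeros(len(df))
    for name in model.covariate_names:
        if name == "hii":
            w = pd.Series({c: e.weight for c, e in cfg.weight_table.entries.items()})
            cols = [c for c in w.index if c in df.columns]
            x = df[cols].fillna(0.0).to_numpy() @ w[cols].to_numpy()
        elif name in values:
            x = values[name]
        elif name in df.columns:
            x = df[name].to_numpy()
        else:
            raise ValueError(
                f"truth-model covariate '{name}' cannot be computed from "
                "generated columns"
            )
        eta = eta + model.coefficients[name] * np.asarray(x, dtype=float)
    return eta


def _sample_ordinal(rng, thresholds, eta) -> np.ndarray:
    cum = expit(np.asarray(thresholds)[None, :] - eta[:, None])
    u = rng.random(len(eta))[:, None]
    return 1 + (u >= cum).sum(axis=1)


def generate(config: GeneratorConfig) -> CohortTable:
    """Draw a cohort from the configured data-generating process.

    Fully reproducible from ``config.seed``: one generator drives the whole
    stream. Ages are uniform within their sampled band; over-70-only
    conditions are missing (never absent) for subjects aged 70 or less;
    SRH is sampled from the truth model *before* missingness is injected,
    so masked covariates remain missing-at-random.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    band_probs = np.asarray([b.prob for b in cfg.age_bands], dtype=float)
    band_probs = band_probs / band_probs.sum()
    band_idx = rng.choice(len(cfg.age_bands), size=n, p=band_probs)
    los = np.asarray([b.lo for b in cfg.age_bands])
    his = np.asarray([b.hi for b in cfg.age_bands])
    ages = np.round(
        rng.uniform(los[band_idx], his[band_idx] + 1.0), 1
    ).clip(max=his[band_idx] + 0.9)
    sex = (rng.random(n) < cfg.sex_prob_male).astype(float)
    frailty = (
        rng.normal(0.0, cfg.frailty_sd, size=n) if cfg.frailty_sd > 0 else np.zeros(n)
    )

    mhi_cat = 1 + rng.choice(4, size=n, p=np.asarray(cfg.mhi_category_probs) / np.sum(cfg.mhi_category_probs))
    means = np.asarray(cfg.mhi_score_means)[mhi_cat - 1]
    sds = np.asarray(cfg.mhi_score_sds)[mhi_cat - 1]
    mhi_score = np.clip(rng.normal(means, sds), 1.0, 4.0)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "sex": sex,
            "age": ages,
            "mhi_score": mhi_score,
            "mhi_category": mhi_cat.astype(float),
        }
    )
    for cid, col in _sample_conditions(rng, cfg, ages, frailty).items():
        df[cid] = col

    eta = _linear_predictor(cfg, df, band_idx)
    thresholds = (
        cfg.condition_truth.thresholds
        if cfg.condition_truth is not None
        else cfg.truth_model.thresholds
    )
    df["srh"] = _sample_ordinal(rng, thresholds, eta).astype(float)

    # missingness injection ("mhi" masks score and category jointly)
    for col, prob in cfg.missingness.items():
        if prob <= 0:
            continue
        mask = rng.random(n) < prob
        targets = ["mhi_score", "mhi_category"] if col == "mhi" else [col]
        for t in targets:
            df.loc[mask, t] = np.nan

    catalog = cfg.catalog or default_catalog()
    return CohortTable(df, catalog)


def with_updates(config: GeneratorConfig, **kwargs) -> GeneratorConfig:
    """Functional config update (dataclasses.replace passthrough)."""
    return replace(config, **kwargs)
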