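"""Predict self-reported health from the index.

The prediction model is a proportional-odds model of SRH on four
covariates: the HII score (continuous), the continuous mental-distress
score (1-4), age in years, and sex (0=female, 1=male). The published fitted
model ships with the package (:func:`published_model`); :func:`fit_hii_model`
refits the same specification on any scored cohort.

Prediction never reads a subject's observed SRH: category probabilities and
the expected SRH come from the covariates alone, so the same code serves
external validation cohorts.
"""

from __future__ import annotations

import json
import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable
from .derivation import WeightTable
from .ordinal import FitReport, OrdinalModel, fit_po
from .scoring import ComorbidityGroups, DEFAULT_GROUPS, cohort_groups, cohort_hii

try:
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _pkg_files  # type: ignore

logger = logging.getLogger(__name__)

#: covariate names of the HII prediction model, in design order
HII_MODEL_COVARIATES = ("hii", "mhi", "age", "sex")


def published_model() -> OrdinalModel:
    """The published HII prediction model (immutable copy per call).

    Thresholds (-10.566, -6.682, -3.330); coefficients hii -0.249,
    mhi -1.915, age -0.048, sex -0.036, under the package's link
    orientation (see the model's ``convention_note``).
    """
    path = _pkg_files("healthimpact").joinpath("data/published_hii_model.json")
    return OrdinalModel.from_dict(json.loads(path.read_text(encoding="utf-8")))


def _model_frame(cohort: CohortTable, weights: Optional[WeightTable]) -> pd.DataFrame:
    """Covariate frame (hii, mhi, age, sex) for the prediction model."""
    df = pd.DataFrame(index=cohort.df.index)
    if weights is not None:
        df["hii"] = cohort_hii(weights, cohort).astype(float)
    df["mhi"] = cohort.df["mhi_score"]
    df["age"] = cohort.df["age"]
    df["sex"] = cohort.df["sex"]
    return df


def fit_hii_model(cohort: CohortTable, weights: WeightTable) -> FitReport:
    """PO fit of SRH on {hii, mhi, age, sex} (listwise deletion)."""
    frame = _model_frame(cohort, weights)
    frame["srh"] = cohort.df["srh"]
    return fit_po(frame, "srh", list(HII_MODEL_COVARIATES))


def predict_srh(
    model: OrdinalModel,
    cohort: CohortTable,
    weights: Optional[WeightTable] = None,
) -> pd.DataFrame:
    """Per-subject category probabilities and expected SRH.

    Returns a frame with subject_id, the computed covariates, p1..pK, the
    expected SRH (the headline prediction) and the modal predicted
    category. Subjects missing a covariate get NaN predictions; their count
    is logged. The observed SRH column is never read.
    """
    frame = _model_frame(cohort, weights)
    names = list(model.covariate_names)
    missing_cols = [n for n in names if n not in frame.columns]
    if missing_cols:
        raise ValueError(
            f"cannot compute covariate(s) {missing_cols}; pass a weight table"
        )
    X = frame[names].to_numpy(dtype=float)
    beta = np.asarray([model.coefficients[n] for n in names])
    ok = ~np.isnan(X).any(axis=1)
    if (~ok).any():
        logger.info("%d subject(s) missing a covariate: NaN predictions", int((~ok).sum()))
    K = model.n_categories
    cum = np.full((len(X), K - 1), np.nan)
    cum[ok] = expit(model.thresholds[None, :] - (X[ok] @ beta)[:, None])
    cum_full = np.concatenate(
        [np.zeros((len(X), 1)), cum, np.ones((len(X), 1))], axis=1
    )
    probs = np.diff(cum_full, axis=1)
    probs[~ok] = np.nan

    out = pd.DataFrame({"subject_id": cohort.df["subject_id"]})
    for n in names:
        out[n] = frame[n]
    for k in range(K):
        out[f"p{k + 1}"] = probs[:, k]
    out["expected_srh"] = probs @ np.arange(1, K + 1)
    modal = np.where(ok, np.argmax(np.nan_to_num(probs, nan=-1.0), axis=1) + 1, np.nan)
    out["predicted_category"] = modal
    return out


def group_summary(
    predictions: pd.DataFrame,
    cohort: CohortTable,
    groups: ComorbidityGroups = DEFAULT_GROUPS,
) -> pd.DataFrame:
    """Observed vs predicted mean SRH per comorbidity group.

    ``predictions`` must carry the ``hii`` covariate column (as produced by
    :func:`predict_srh` with a weight table). Groups with no subjects get
    n=0 and missing means.
    """
    if "hii" not in predictions.columns:
        raise ValueError("predictions frame lacks an 'hii' column")
    hii = predictions["hii"]
    labels = cohort_groups(groups, hii.fillna(-1).astype(int).clip(lower=0)).where(
        hii.notna()
    )
    observed = cohort.df["srh"]
    predicted = predictions["expected_srh"]
    rows = []
    for b in groups.bins:
        in_group = (labels == b.label) & observed.notna() & predicted.notna()
        n = int(in_group.sum())
        rows.append(
            {
                "group": b.label,
                "n": n,
                "observed_mean_srh": float(observed[in_group].mean()) if n else np.nan,
                "predicted_mean_srh": float(predicted[in_group].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
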