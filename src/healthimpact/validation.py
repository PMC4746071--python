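"""Rank-based validation statistics and cohort descriptives.

Implements the validation toolkit for an SRH-anchored comorbidity index:
Spearman correlations of each index with observed SRH (full sample and the
ill-only subsample), a Wilcoxon signed-rank comparison of predicted and
observed SRH, and nonparametric group descriptives (Mann-Whitney /
Kruskal-Wallis).

The Wilcoxon implementation drops zero differences, average-ranks tied
absolute differences, and uses the tie-corrected normal approximation for
n > 25 with exact enumeration of the null distribution (via a
generating-function convolution over the rank sums) for n <= 25. Spearman
rho uses average ranks; its p-value is exact (exhaustive permutation) for
n <= 10 and the large-sample t approximation otherwise. All p-values are
two-sided.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .derivation import age_band_column

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- spearman


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    note: str = ""


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Pairwise-complete filtering; exact permutation p for n <= 10, t
    approximation otherwise. Constant input flags rho as undefined.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(np.nan, np.nan, n, note="constant input")
    rho, p_approx = stats.spearmanr(x, y)
    if n <= 10:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(p_approx)
    return SpearmanResult(float(rho), p, n)


def _spearman_exact_p(x, y, rho_obs: float) -> float:
    """Two-sided exact permutation p over all n! orderings of y."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    n = len(rx)
    hits = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            r = (ry_c[np.asarray(chunk)] @ rx_c) / denom
            hits += int(np.sum(np.abs(r) >= target))
            total += len(chunk)
            chunk = []
    if chunk:
        r = (ry_c[np.asarray(chunk)] @ rx_c) / denom
        hits += int(np.sum(np.abs(r) >= target))
        total += len(chunk)
    return hits / total


# ---------------------------------------------------------------- wilcoxon


@dataclass
class WilcoxonResult:
    z: float
    p: float
    n_pairs: int
    degenerate: bool = False


def wilcoxon_signed_rank(a, b, exact_max_n: int = 25) -> WilcoxonResult:
    """Wilcoxon signed-rank test on matched pairs (two-sided).

    Zero differences are dropped; tied absolute differences get average
    ranks. The z statistic always comes from the tie-corrected normal
    approximation; the p-value is exact (tie-aware enumeration) when the
    number of nonzero pairs is <= ``exact_max_n``.
    """
    a, b = _pairwise_complete(a, b)
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(z=0.0, p=1.0, n_pairs=0, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if sigma2 <= 0 else (w_plus - mu) / np.sqrt(sigma2)
    if sigma2 <= 0:
        return WilcoxonResult(z=0.0, p=1.0, n_pairs=n, degenerate=True)
    if n <= exact_max_n:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(z=float(z), p=min(1.0, p), n_pairs=n)


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by convolving the signed-rank generating function.

    Ranks are doubled so average ranks (.5 steps) become integers; the null
    distribution of 2*W+ is built by the polynomial product of
    (1 + x^(2r_i)) / 2 over pairs, and symmetry around its mean gives the
    two-sided tail.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    top = 0
    for r in r2:
        new = pmf.copy()
        new[r : top + r + 1] += pmf[: top + 1]
        pmf = new
        top += r
    pmf /= pmf.sum()
    w2 = int(round(2 * w_plus))
    mu2 = total / 2.0
    dev = abs(w2 - mu2) - 1e-9
    support = np.arange(total + 1)
    return float(pmf[np.abs(support - mu2) >= dev].sum())


# ----------------------------------------------------------- ill-only test


@dataclass
class IllOnlyContrast:
    """Index-vs-SRH correlations on the full sample and the ill subsample."""

    hii_full: SpearmanResult
    hii_ill: Optional[SpearmanResult]
    cci_full: SpearmanResult
    cci_ill: Optional[SpearmanResult]
    hii_direction: str = ""
    cci_direction: str = ""


def _direction(full: SpearmanResult, ill: Optional[SpearmanResult]) -> str:
    if ill is None or np.isnan(ill.rho) or np.isnan(full.rho):
        return "undefined"
    if abs(ill.rho) > abs(full.rho):
        return "strengthened"
    if abs(ill.rho) < abs(full.rho):
        return "attenuated"
    return "unchanged"


def ill_only_contrast(hii_scores, cci_scores, srh) -> IllOnlyContrast:
    """Spearman of each index with SRH, full sample vs index>0 subsample.

    The ill subsample for each index is the subjects that index itself
    classifies as ill (score > 0). Empty or constant subsamples are
    flagged rather than erroring.
    """
    hii = np.asarray(hii_scores, dtype=float)
    cci = np.asarray(cci_scores, dtype=float)
    srh = np.asarray(srh, dtype=float)

    def _subsample(index):
        mask = index > 0
        if mask.sum() < 3:
            logger.warning("ill-only subsample has <3 subjects; flagged")
            return None
        try:
            return spearman(index[mask], srh[mask])
        except ValueError:
            return None

    out = IllOnlyContrast(
        hii_full=spearman(hii, srh),
        hii_ill=_subsample(hii),
        cci_full=spearman(cci, srh),
        cci_ill=_subsample(cci),
    )
    out.hii_direction = _direction(out.hii_full, out.hii_ill)
    out.cci_direction = _direction(out.cci_full, out.cci_ill)
    return out


# ------------------------------------------------------------- descriptives


def descriptive_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-variable SRH descriptives with nonparametric contrasts.

    One row per group level: count, mean and SD of SRH, plus a Mann-Whitney
    p (binary splits: each condition present-vs-absent, sex) or a
    Kruskal-Wallis p (age bands, mental-health categories). Tie corrections
    are those of the scipy implementations. Levels with no subjects are
    skipped with a note row.
    """
    df = cohort.df
    srh = df["srh"]
    rows = []

    def _stats(mask):
        vals = srh[mask & srh.notna()]
        return len(vals), (vals.mean() if len(vals) else np.nan), (
            vals.std(ddof=1) if len(vals) > 1 else np.nan
        )

    def _mw(mask_a, mask_b):
        a = srh[mask_a & srh.notna()]
        b = srh[mask_b & srh.notna()]
        if len(a) == 0 or len(b) == 0:
            return np.nan
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    # conditions: present vs absent
    for cid in cohort.catalog.ids:
        present = df[cid] == 1
        absent = df[cid] == 0
        n, m, s = _stats(present)
        if n == 0:
            rows.append(
                {"variable": cid, "level": "present", "count": 0, "mean_srh": np.nan,
                 "sd_srh": np.nan, "test": "mann-whitney", "p": np.nan,
                 "note": "no cases"}
            )
            continue
        rows.append(
            {"variable": cid, "level": "present", "count": n, "mean_srh": m,
             "sd_srh": s, "test": "mann-whitney", "p": _mw(present, absent),
             "note": ""}
        )

    # sex
    p_sex = _mw(df["sex"] == 0, df["sex"] == 1)
    for level, mask in (("female", df["sex"] == 0), ("male", df["sex"] == 1)):
        n, m, s = _stats(mask)
        rows.append(
            {"variable": "sex", "level": level, "count": n, "mean_srh": m,
             "sd_srh": s, "test": "mann-whitney", "p": p_sex, "note": ""}
        )

    # multi-level: age bands and mental-health category
    bands = age_band_column(df["age"])
    for var, series in (("age_band", bands), ("mhi_category", df["mhi_category"])):
        levels = [lv for lv in pd.unique(series.dropna())]
        groups = [srh[(series == lv) & srh.notna()] for lv in levels]
        groups = [g for g in groups if len(g)]
        p_kw = (
            float(stats.kruskal(*groups).pvalue)
            if len(groups) >= 2 and any(g.nunique() > 1 for g in groups)
            else np.nan
        )
        for lv in sorted(levels, key=str):
            n, m, s = _stats(series == lv)
            rows.append(
                {"variable": var, "level": str(lv), "count": n, "mean_srh": m,
                 "sd_srh": s, "test": "kruskal-wallis", "p": p_kw, "note": ""}
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- full report


@dataclass
class ValidationReport:
    """Headline validation statistics for one cohort."""

    spearman_hii: SpearmanResult
    spearman_hii_ill_only: Optional[SpearmanResult]
    spearman_cci: SpearmanResult
    spearman_cci_ill_only: Optional[SpearmanResult]
    wilcoxon: WilcoxonResult
    group_table: pd.DataFrame
    hii_direction: str = ""
    cci_direction: str = ""

    def to_dict(self) -> dict:
        def _sp(r):
            if r is None:
                return None
            return {"rho": r.rho, "p": r.p, "n": r.n, "note": r.note}

        return {
            "spearman_hii": _sp(self.spearman_hii),
            "spearman_hii_ill_only": _sp(self.spearman_hii_ill_only),
            "spearman_cci": _sp(self.spearman_cci),
            "spearman_cci_ill_only": _sp(self.spearman_cci_ill_only),
            "wilcoxon": {
                "z": self.wilcoxon.z,
                "p": self.wilcoxon.p,
                "n_pairs": self.wilcoxon.n_pairs,
                "degenerate": self.wilcoxon.degenerate,
            },
            "hii_direction": self.hii_direction,
            "cci_direction": self.cci_direction,
            "group_table": self.group_table.to_dict(orient="records"),
        }


def validate_predictions(
    cohort: CohortTable,
    predictions: pd.DataFrame,
    hii_scores,
    cci_scores,
    groups=None,
) -> ValidationReport:
    """Assemble the full validation report for a scored, predicted cohort."""
    from .prediction import group_summary
    from .scoring import DEFAULT_GROUPS

    groups = groups or DEFAULT_GROUPS
    srh = cohort.df["srh"].to_numpy(dtype=float)
    contrast = ill_only_contrast(hii_scores, cci_scores, srh)
    wil = wilcoxon_signed_rank(srh, predictions["expected_srh"].to_numpy(dtype=float))
    table = group_summary(predictions, cohort, groups)
    return ValidationReport(
        spearman_hii=contrast.hii_full,
        spearman_hii_ill_only=contrast.hii_ill,
        spearman_cci=contrast.cci_full,
        spearman_cci_ill_only=contrast.cci_ill,
        wilcoxon=wil,
        group_table=table,
        hii_direction=contrast.hii_direction,
        cci_direction=contrast.cci_direction,
    )
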