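"""Apply condition weights to subjects: HII score, comorbidity groups, and
the Charlson comparator.

The Health Impact Index (HII) of a subject is the sum of the weights of the
conditions the subject reports; missing condition status scores as absent
(logged), because validation needs a number for every subject. The Charlson
Comorbidity Index (CCI) comparator uses a configurable condition-to-weight
map restricted to survey items with a Charlson analogue, with category-level
deduplication (e.g. two chronic-pulmonary diagnoses count once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import CohortTable, SubjectRecord

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------- groups


@dataclass(frozen=True)
class GroupBin:
    label: str
    lo: int
    hi: Optional[int]  # None = unbounded above

    def __contains__(self, score: int) -> bool:
        return score >= self.lo and (self.hi is None or score <= self.hi)


@dataclass(frozen=True)
class ComorbidityGroups:
    """Ordered, contiguous score bins covering 0..infinity."""

    bins: tuple[GroupBin, ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("at least one bin required")
        expect = 0
        for i, b in enumerate(self.bins):
            if b.lo != expect:
                raise ValueError(f"bins not contiguous at score {expect}")
            last = i == len(self.bins) - 1
            if last:
                if b.hi is not None:
                    raise ValueError("last bin must be unbounded above")
            else:
                if b.hi is None or b.hi < b.lo:
                    raise ValueError(f"bad bin {b.label}")
                expect = b.hi + 1

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.bins)


#: Not ill (0), Mildly ill (1-2), Moderately ill (3-5), Seriously ill (>=6)
DEFAULT_GROUPS = ComorbidityGroups(
    (
        GroupBin("Not ill", 0, 0),
        GroupBin("Mildly ill", 1, 2),
        GroupBin("Moderately ill", 3, 5),
        GroupBin("Seriously ill", 6, None),
    )
)


def assign_group(groups: ComorbidityGroups, score: int) -> str:
    """Label of the unique bin containing ``score`` (score must be >=0)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    for b in groups.bins:
        if score in b:
            return b.label
    raise AssertionError("bins must cover all non-negative scores")


# ---------------------------------------------------------------------- HII


def _present_conditions(record) -> set:
    if isinstance(record, SubjectRecord):
        items = record.conditions.items()
    else:
        items = record.items()
    present, missing = set(), 0
    for cid, status in items:
        if status is None or (isinstance(status, float) and np.isnan(status)):
            missing += 1
            continue
        if bool(status):
            present.add(cid)
    if missing:
        logger.debug("%d missing condition status(es) scored as absent", missing)
    return present


def compute_hii(weights, record) -> int:
    """HII score: sum of table weights over the subject's present conditions.

    ``record`` is a :class:`SubjectRecord` or a mapping condition_id ->
    present/absent/missing. Conditions not in the weight table contribute 0;
    missing statuses score as absent.
    """
    present = _present_conditions(record)
    return int(sum(weights.entries[c].weight for c in present if c in weights.entries))


def cohort_hii(weights, cohort: CohortTable) -> pd.Series:
    """Vectorized HII per subject (missing statuses score as absent)."""
    w = pd.Series(
        {c: e.weight for c, e in weights.entries.items()}, dtype=float
    )
    cols = [c for c in w.index if c in cohort.df.columns]
    n_missing = int(cohort.df[cols].isna().to_numpy().sum())
    if n_missing:
        logger.debug("%d missing condition cells scored as absent", n_missing)
    scores = cohort.df[cols].fillna(0.0).to_numpy() @ w[cols].to_numpy()
    return pd.Series(scores.astype(int), index=cohort.df.index, name="hii")


# ---------------------------------------------------------------------- CCI


@dataclass(frozen=True)
class CharlsonEntry:
    weight: int
    category: str


@dataclass(frozen=True)
class CharlsonMap:
    """Survey-condition -> Charlson weight map with category dedup.

    Within one Charlson category only the highest weight among the present
    conditions counts. Weights must come from the classic set {1, 2, 3, 6}.
    """

    entries: Mapping[str, CharlsonEntry]

    def __post_init__(self) -> None:
        bad = {c: e.weight for c, e in self.entries.items() if e.weight not in (1, 2, 3, 6)}
        if bad:
            raise ValueError(f"non-classic Charlson weight(s): {bad}")


#: Our documented default operationalization for this survey's items. The
#: source study reports CCI correlations without printing its mapping; this
#: map is the package's own, restricted to conditions with a Charlson
#: analogue, and fully configurable.
DEFAULT_CHARLSON_MAP = CharlsonMap(
    {
        "myocardial_infarction": CharlsonEntry(1, "myocardial_infarction"),
        "cerebrovascular_stroke": CharlsonEntry(1, "cerebrovascular_disease"),
        "diabetes": CharlsonEntry(1, "diabetes"),
        "ventricular_ulcer": CharlsonEntry(1, "ulcer_disease"),
        "duodenal_ulcer": CharlsonEntry(1, "ulcer_disease"),
        "chronic_bronchitis": CharlsonEntry(1, "chronic_pulmonary"),
        "asthma": CharlsonEntry(1, "chronic_pulmonary"),
        "rheumatoid_arthritis": CharlsonEntry(1, "connective_tissue"),
        "liver_disease": CharlsonEntry(1, "mild_liver_disease"),
        "cancer_survivor": CharlsonEntry(2, "malignancy"),
    }
)


def compute_cci(cmap: CharlsonMap, record) -> int:
    """Charlson score with category-level dedup (missing scores as absent)."""
    present = _present_conditions(record)
    per_category: dict = {}
    for cid in present:
        entry = cmap.entries.get(cid)
        if entry is None:
            continue
        per_category[entry.category] = max(
            per_category.get(entry.category, 0), entry.weight
        )
    return int(sum(per_category.values()))


def cohort_cci(cmap: CharlsonMap, cohort: CohortTable) -> pd.Series:
    """Vectorized CCI per subject."""
    categories: dict = {}
    for cid, entry in cmap.entries.items():
        if cid in cohort.df.columns:
            categories.setdefault(entry.category, []).append((cid, entry.weight))
    total = np.zeros(len(cohort), dtype=int)
    for conds in categories.values():
        cat_score = np.zeros(len(cohort), dtype=int)
        for cid, w in conds:
            present = cohort.df[cid].fillna(0.0).to_numpy() > 0
            cat_score = np.maximum(cat_score, np.where(present, w, 0))
        total += cat_score
    return pd.Series(total, index=cohort.df.index, name="cci")


def cohort_groups(
    groups: ComorbidityGroups, scores: Union[pd.Series, Sequence[int]]
) -> pd.Series:
    """Vectorized group labels for a score vector."""
    s = pd.Series(scores)
    return s.map(lambda v: assign_group(groups, int(v))).rename("hii_group")
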