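"""Survey-cohort data model and delimited-text I/O.

A cohort is one row per subject: sex, age, a mental-distress score
(continuous mean score on the 1--4 scale and/or a 4-level symptom category),
binary indicators for ~30 self-reported chronic conditions, and the 4-level
self-reported health rating (SRH, 1=poor ... 4=very good).

Condition status is tri-state: present / absent / missing. Six conditions
are asked only of participants older than 70 years; for younger subjects
their status is *missing* (they were never asked), never absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

try:  # importlib.resources for bundled data
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _pkg_files  # type: ignore

logger = logging.getLogger(__name__)

#: standard (non-condition) columns of a cohort file, in canonical order
STANDARD_COLUMNS = ("subject_id", "sex", "age", "mhi_score", "mhi_category", "srh")
MANDATORY_COLUMNS = ("subject_id", "sex", "age", "srh")

_TRUE_TOKENS = {"1", "1.0", "yes", "y", "true", "t", "present"}
_FALSE_TOKENS = {"0", "0.0", "no", "n", "false", "f", "absent"}
_NA_TOKENS = {"", ".", "na", "n/a", "nan", "none", "missing", "null"}
_FEMALE_TOKENS = {"0", "0.0", "f", "female", "woman", "w"}
_MALE_TOKENS = {"1", "1.0", "m", "male", "man"}


@dataclass(frozen=True)
class CatalogEntry:
    condition_id: str
    label: str
    age_restricted: bool = False
    charlson_category: Optional[str] = None


@dataclass(frozen=True)
class ConditionCatalog:
    """Catalog of the survey's condition items.

    ``age_restricted`` marks items asked only of participants older than
    70 years.
    """

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.condition_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("condition_id values must be unique")
        if any(not i for i in ids):
            raise ValueError("condition_id values must be non-empty")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(e.condition_id for e in self.entries)

    @property
    def age_restricted_ids(self) -> tuple[str, ...]:
        return tuple(e.condition_id for e in self.entries if e.age_restricted)

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self.ids

    def __getitem__(self, condition_id: str) -> CatalogEntry:
        for e in self.entries:
            if e.condition_id == condition_id:
                return e
        raise KeyError(condition_id)

    @classmethod
    def from_yaml(cls, path) -> "ConditionCatalog":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ConditionCatalog":
        entries = tuple(
            CatalogEntry(
                condition_id=item["id"],
                label=item.get("label", item["id"]),
                age_restricted=bool(item.get("age_restricted", False)),
                charlson_category=item.get("charlson_category"),
            )
            for item in doc["conditions"]
        )
        return cls(entries)


def default_catalog() -> ConditionCatalog:
    """The bundled default catalog (all conditions of the source survey)."""
    path = _pkg_files("healthimpact").joinpath("data/condition_catalog.yaml")
    return ConditionCatalog.from_dict(yaml.safe_load(path.read_text(encoding="utf-8")))


@dataclass
class SubjectRecord:
    """One subject. ``None``/NaN encodes missing; conditions map to
    True (present) / False (absent) / None (missing)."""

    subject_id: str
    sex: Optional[int]
    age_years: Optional[float]
    mhi_score: Optional[float] = None
    mhi_category: Optional[int] = None
    conditions: dict = field(default_factory=dict)
    srh: Optional[int] = None


def _opt(value):
    if value is None:
        return np.nan
    if isinstance(value, float) and np.isnan(value):
        return np.nan
    return value


class CohortTable:
    """A cohort: per-subject records plus the condition catalog.

    Internally a :class:`pandas.DataFrame` with the standard columns and one
    float column per catalog condition (1.0 present, 0.0 absent, NaN
    missing). The frame always carries *every* catalog condition column.
    """

    def __init__(self, df: pd.DataFrame, catalog: ConditionCatalog):
        df = df.copy()
        for col in STANDARD_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        extra = [
            c for c in df.columns if c not in STANDARD_COLUMNS and c not in catalog.ids
        ]
        if extra:
            raise ValueError(
                f"condition column(s) not in catalog: {', '.join(sorted(extra))}"
            )
        for cid in catalog.ids:
            if cid not in df.columns:
                df[cid] = np.nan
        df = df[list(STANDARD_COLUMNS) + list(catalog.ids)]
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject_id: {dupes[:5]}")
        df = df.reset_index(drop=True)
        self._df = df
        self.catalog = catalog

    # ------------------------------------------------------------------ basic
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CohortTable(n={len(self)}, conditions={len(self.catalog.ids)})"

    @property
    def records(self) -> list[SubjectRecord]:
        out = []
        for row in self._df.itertuples(index=False):
            d = row._asdict()
            conditions = {}
            for cid in self.catalog.ids:
                v = d[cid]
                conditions[cid] = None if pd.isna(v) else bool(v)
            out.append(
                SubjectRecord(
                    subject_id=str(d["subject_id"]),
                    sex=None if pd.isna(d["sex"]) else int(d["sex"]),
                    age_years=None if pd.isna(d["age"]) else float(d["age"]),
                    mhi_score=None if pd.isna(d["mhi_score"]) else float(d["mhi_score"]),
                    mhi_category=(
                        None if pd.isna(d["mhi_category"]) else int(d["mhi_category"])
                    ),
                    conditions=conditions,
                    srh=None if pd.isna(d["srh"]) else int(d["srh"]),
                )
            )
        return out

    @classmethod
    def from_records(
        cls, records: Iterable[SubjectRecord], catalog: ConditionCatalog
    ) -> "CohortTable":
        rows = []
        for r in records:
            row = {
                "subject_id": r.subject_id,
                "sex": _opt(r.sex),
                "age": _opt(r.age_years),
                "mhi_score": _opt(r.mhi_score),
                "mhi_category": _opt(r.mhi_category),
                "srh": _opt(r.srh),
            }
            for cid in catalog.ids:
                v = r.conditions.get(cid)
                row[cid] = np.nan if v is None else float(v)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(STANDARD_COLUMNS) + list(catalog.ids))
        return cls(df, catalog)

    def subset(self, mask) -> "CohortTable":
        """Row-subset (order preserved); mask is boolean over rows."""
        return CohortTable(self._df.loc[np.asarray(mask, dtype=bool)], self.catalog)


# -------------------------------------------------------------------- parsing


def _parse_binary(raw: str, true_tokens, false_tokens, na_tokens) -> float:
    s = raw.strip().lower()
    if s in na_tokens:
        return np.nan
    if s in true_tokens:
        return 1.0
    if s in false_tokens:
        return 0.0
    return np.nan  # unparseable -> missing (caller logs)


def _parse_float(raw: str, na_tokens) -> float:
    s = raw.strip().lower()
    if s in na_tokens:
        return np.nan
    try:
        return float(s)
    except ValueError:
        return np.nan


def read_cohort(
    path,
    catalog: Optional[ConditionCatalog] = None,
    dialect: Optional[Mapping] = None,
) -> CohortTable:
    """Read a delimited cohort file (CSV/TSV with a header row).

    Tolerant of 0/1, yes/no and true/false encodings; unparseable or
    out-of-range cells become missing with a logged warning. Missing
    mandatory columns and duplicate subject ids are hard errors, as is any
    condition column not found in the catalog.
    """
    catalog = catalog or default_catalog()
    dialect = dict(dialect or {})
    sep = dialect.get("sep")
    true_tokens = _TRUE_TOKENS | {
        str(t).lower() for t in dialect.get("true_values", ())
    }
    false_tokens = _FALSE_TOKENS | {
        str(t).lower() for t in dialect.get("false_values", ())
    }
    na_tokens = _NA_TOKENS | {str(t).lower() for t in dialect.get("na_values", ())}

    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"mandatory column missing from cohort file: '{col}'")
    unknown = [
        c for c in raw.columns if c not in STANDARD_COLUMNS and c not in catalog.ids
    ]
    if unknown:
        raise ValueError(
            f"condition column(s) not in catalog: {', '.join(sorted(unknown))}"
        )
    if raw["subject_id"].duplicated().any():
        dupes = raw.loc[raw["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id: {dupes[:5]}")

    n_bad = {}
    df = pd.DataFrame()
    df["subject_id"] = raw["subject_id"].astype(str)

    sex = raw["sex"].map(
        lambda s: _parse_binary(s, _MALE_TOKENS, _FEMALE_TOKENS, na_tokens)
    ).astype(float)
    n_bad["sex"] = int(sex.isna().sum() - raw["sex"].str.strip().str.lower().isin(na_tokens).sum())
    df["sex"] = sex

    df["age"] = raw["age"].map(lambda s: _parse_float(s, na_tokens)).astype(float)

    for col, lo, hi, as_int in (
        ("mhi_score", 1.0, 4.0, False),
        ("mhi_category", 1, 4, True),
        ("srh", 1, 4, True),
    ):
        if col in raw.columns:
            vals = raw[col].map(lambda s: _parse_float(s, na_tokens)).astype(float)
            bad = vals.notna() & ((vals < lo) | (vals > hi))
            if as_int:
                nonint = vals.notna() & (vals != vals.round())
                bad |= nonint
            if bad.any():
                logger.warning(
                    "%d out-of-range value(s) in column '%s' coerced to missing",
                    int(bad.sum()),
                    col,
                )
            vals = vals.mask(bad)
            df[col] = vals
        else:
            df[col] = np.nan

    for cid in catalog.ids:
        if cid in raw.columns:
            df[cid] = raw[cid].map(
                lambda s: _parse_binary(s, true_tokens, false_tokens, na_tokens)
            ).astype(float)
        else:
            df[cid] = np.nan

    # age-restricted items were never asked below/at 70: force missing
    young = df["age"].isna() | (df["age"] <= 70)
    for cid in catalog.age_restricted_ids:
        coerced = young & df[cid].notna()
        if coerced.any():
            logger.warning(
                "%d value(s) for age-restricted condition '%s' on subjects <=70y "
                "coerced to missing",
                int(coerced.sum()),
                cid,
            )
            df.loc[coerced, cid] = np.nan

    if n_bad.get("sex", 0) > 0:
        logger.warning("%d unparseable 'sex' value(s) coerced to missing", n_bad["sex"])
    return CohortTable(df, catalog)


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    """Write a cohort as delimited text; ``read_cohort`` round-trips it."""
    df = cohort.df.copy()
    for col in ("sex", "mhi_category", "srh"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    for cid in cohort.catalog.ids:
        df[cid] = df[cid].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep=sep, index=False, na_rep="")


_COLUMN_ALIASES = {"mhi": "mhi_score", "age_years": "age"}


def complete_cases(cohort: CohortTable, variables: Sequence[str]) -> CohortTable:
    """Subjects with no missing value in any of ``variables`` (order kept).

    ``variables`` are cohort column ids (``mhi`` is accepted as an alias for
    ``mhi_score``). Idempotent; never increases the record count.
    """
    cols = []
    for v in variables:
        col = _COLUMN_ALIASES.get(v, v)
        if col not in cohort.df.columns:
            raise ValueError(f"unknown variable: '{v}'")
        cols.append(col)
    if not cols:
        return CohortTable(cohort.df, cohort.catalog)
    mask = cohort.df[cols].notna().all(axis=1)
    return cohort.subset(mask.to_numpy())
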