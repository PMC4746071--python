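"""Index derivation: stepwise model families, OR extraction, exclusion and
rounding rules, weight tables.

The derivation pipeline mirrors how the published index was built from a
reference cohort:

1. *Unadjusted models*: one single-covariate PO model of SRH per condition
   (and for age bands, sex, mental-health category).
2. *Base model*: all conditions jointly (each controlled for the others).
3. *Mental-health model*: base plus the 4-level mental-distress category.
4. *Full contextual model*: mental-health model plus 10-year age bands and
   sex. Conditions asked only of the over-70s are fitted in a separate full
   model restricted to subjects older than 70.
5. Conditions whose full-contextual OR (of reporting lower SRH) is <= 1.2
   are excluded; the rest get weight = OR rounded to the nearest natural
   number (half-up).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .cohort import CohortTable
from .ordinal import Categorical, FitReport, fit_po, odds_ratios

try:
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _pkg_files  # type: ignore

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSION_OR = 1.2
DEFAULT_AGE_EDGES = (25, 30, 40, 50, 60, 70, 80)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with .5 rounding away from zero."""
    return int(math.floor(x + 0.5))


def round_half_even(x: float) -> int:
    return int(round(x))


_ROUNDERS = {"half-up": round_half_up, "half-even": round_half_even}


# ------------------------------------------------------------- weight table


@dataclass(frozen=True)
class WeightEntry:
    weight: int
    source_or: float
    source_model: str  # "main" | "over70"
    override: bool = False  # kept despite failing the exclusion rule

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("weights must be >= 1")


@dataclass
class WeightTable:
    """Condition -> integer weight, with provenance ORs for audit."""

    entries: dict  # condition_id -> WeightEntry
    excluded: dict = field(default_factory=dict)  # condition_id -> source OR

    def weight_of(self, condition_id: str) -> int:
        return self.entries[condition_id].weight

    @property
    def total_weight(self) -> int:
        return sum(e.weight for e in self.entries.values())

    # -------------------------------------------------------- serialization
    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["condition_id", "weight", "source_or", "source_model", "override"])
            for cid, e in self.entries.items():
                w.writerow([cid, e.weight, e.source_or, e.source_model, str(e.override).lower()])

    @classmethod
    def from_csv(cls, path) -> "WeightTable":
        entries = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries[row["condition_id"]] = WeightEntry(
                    weight=int(row["weight"]),
                    source_or=float(row["source_or"]),
                    source_model=row.get("source_model", "main"),
                    override=row.get("override", "false").strip().lower()
                    in ("true", "1", "yes"),
                )
        return cls(entries=entries)

    def to_yaml(self, path) -> None:
        doc = {
            "entries": {
                cid: {
                    "weight": e.weight,
                    "source_or": e.source_or,
                    "source_model": e.source_model,
                    "override": e.override,
                }
                for cid, e in self.entries.items()
            },
            "excluded": {cid: float(v) for cid, v in self.excluded.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WeightTable":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        entries = {
            cid: WeightEntry(
                weight=int(d["weight"]),
                source_or=float(d["source_or"]),
                source_model=d.get("source_model", "main"),
                override=bool(d.get("override", False)),
            )
            for cid, d in doc.get("entries", {}).items()
        }
        return cls(entries=entries, excluded=dict(doc.get("excluded", {})))


def published_weights() -> WeightTable:
    """The published 19-condition weight table, shipped verbatim.

    Note: hypersensitivity is flagged ``override`` because its printed
    full-contextual OR is exactly 1.20, which the printed exclusion rule
    (OR <= 1.2) would drop; the published table nevertheless assigns it
    weight 1 (its unrounded OR presumably exceeded 1.20).
    """
    path = _pkg_files("healthimpact").joinpath("data/published_weights.csv")
    entries = {}
    for row in csv.DictReader(path.read_text(encoding="utf-8").splitlines()):
        entries[row["condition_id"]] = WeightEntry(
            weight=int(row["weight"]),
            source_or=float(row["source_or"]),
            source_model=row["source_model"],
            override=row["override"].strip().lower() == "true",
        )
    return WeightTable(entries=entries)


def published_derivation_ors() -> pd.DataFrame:
    """The published per-condition ORs of the four model families.

    Columns: condition_id, count, unadjusted, base, mental, full_contextual,
    source_model ("over70" for the six conditions asked only of over-70s).
    """
    path = _pkg_files("healthimpact").joinpath("data/published_derivation_ors.csv")
    import io

    return pd.read_csv(io.StringIO(path.read_text(encoding="utf-8")))


# ------------------------------------------------------------ derivation


@dataclass
class DerivationConfig:
    exclusion_or: float = DEFAULT_EXCLUSION_OR
    rounding: str = "half-up"
    age_edges: Sequence[int] = DEFAULT_AGE_EDGES
    min_condition_cases: int = 5
    overrides: Sequence[str] = ()  # conditions kept despite OR <= threshold

    @classmethod
    def from_yaml(cls, path) -> "DerivationConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class StepwiseResults:
    """Fit reports of the four model families (plus the over-70 full model).

    Families that could not be fitted (e.g. no mental-health column) are
    ``None`` with the exception recorded in ``errors``.
    """

    unadjusted: dict  # variable -> FitReport
    base: Optional[FitReport]
    mental: Optional[FitReport]
    full_contextual: Optional[FitReport]
    over70_full: Optional[FitReport]
    condition_ids: tuple = ()  # conditions in the main families
    over70_condition_ids: tuple = ()  # conditions in the over-70 family
    errors: dict = field(default_factory=dict)


def age_band_column(
    ages: pd.Series, edges: Sequence[int] = DEFAULT_AGE_EDGES
) -> pd.Series:
    """10-year age-band labels ('25-29', ..., '80+') from age in years."""
    edges = list(edges)
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f"{edges[-1]}+")
    bins = [-float("inf")] + edges[1:] + [float("inf")]
    return pd.cut(ages, bins=bins, labels=labels, right=False).astype(object).where(
        ages.notna()
    )


def _usable_conditions(df: pd.DataFrame, ids, min_cases: int) -> list:
    out, dropped = [], []
    for cid in ids:
        col = df[cid]
        n_present = int((col == 1).sum())
        n_absent = int((col == 0).sum())
        if n_present >= min_cases and n_absent >= min_cases:
            out.append(cid)
        else:
            dropped.append(cid)
    if dropped:
        logger.warning(
            "condition(s) dropped from joint models (too few cases): %s",
            ", ".join(dropped),
        )
    return out


ALL_FAMILIES = ("unadjusted", "base", "mental", "full_contextual", "over70_full")


def run_stepwise(
    cohort: CohortTable,
    config: Optional[DerivationConfig] = None,
    families: Sequence[str] = ALL_FAMILIES,
) -> StepwiseResults:
    """Fit the unadjusted / base / mental / full-contextual families.

    Age enters the full models as 10-year bands (youngest band is the
    reference), mental health as the 4-level category (level 1, "no
    symptoms", is the reference). Conditions asked only of the over-70s are
    fitted in a separate full model on the over-70 subcohort. ``families``
    restricts which model families are fitted (all by default).
    """
    config = config or DerivationConfig()
    families = set(families)
    unknown = families - set(ALL_FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")
    df = cohort.df.copy()
    df["age_band"] = age_band_column(df["age"], config.age_edges)
    catalog = cohort.catalog
    restricted = set(catalog.age_restricted_ids)
    main_ids = _usable_conditions(
        df, [c for c in catalog.ids if c not in restricted], config.min_condition_cases
    )
    if not any(int((df[c] == 1).sum()) >= 20 for c in main_ids):
        raise ValueError("cohort needs at least one condition with >= 20 cases")

    mental_cov = Categorical("mhi_category", 1)
    age_cov = Categorical("age_band", f"{config.age_edges[0]}-{config.age_edges[1] - 1}")

    results = StepwiseResults(
        unadjusted={}, base=None, mental=None, full_contextual=None, over70_full=None
    )

    over70 = df[df["age"] > 70]
    over70_ids = (
        _usable_conditions(over70, list(catalog.ids), config.min_condition_cases)
        if len(over70)
        else []
    )
    results.condition_ids = tuple(main_ids)
    results.over70_condition_ids = tuple(over70_ids)

    # --- unadjusted: one model per variable -------------------------------
    if "unadjusted" in families:
        for cid in main_ids:
            try:
                results.unadjusted[cid] = fit_po(df, "srh", [cid])
            except Exception as exc:  # record and continue
                results.errors[f"unadjusted:{cid}"] = exc
        for cid in sorted(restricted & set(over70_ids)):
            try:
                results.unadjusted[cid] = fit_po(over70, "srh", [cid])
            except Exception as exc:
                results.errors[f"unadjusted:{cid}"] = exc
        for name, cov in (
            ("age", age_cov), ("sex", "sex"), ("mental_health", mental_cov)
        ):
            try:
                results.unadjusted[name] = fit_po(df, "srh", [cov])
            except Exception as exc:
                results.errors[f"unadjusted:{name}"] = exc

    # --- joint families ----------------------------------------------------
    def _family(name, frame, covs):
        try:
            return fit_po(frame, "srh", covs)
        except Exception as exc:
            results.errors[name] = exc
            logger.warning("family '%s' failed: %s", name, exc)
            return None

    if "base" in families:
        results.base = _family("base", df, list(main_ids))
    if "mental" in families:
        results.mental = _family("mental", df, list(main_ids) + [mental_cov])
    if "full_contextual" in families:
        results.full_contextual = _family(
            "full_contextual", df, list(main_ids) + [mental_cov, age_cov, "sex"]
        )
    if "over70_full" in families and over70_ids:
        over70_age = Categorical("age_band", f"{config.age_edges[-2]}-{config.age_edges[-1] - 1}")
        results.over70_full = _family(
            "over70_full", over70, list(over70_ids) + [mental_cov, over70_age, "sex"]
        )
    return results


def weights_from_ors(
    full_ors: Mapping[str, float],
    over70_ors: Optional[Mapping[str, float]] = None,
    exclusion_or: float = DEFAULT_EXCLUSION_OR,
    rounding: str = "half-up",
    overrides: Sequence[str] = (),
) -> WeightTable:
    """Apply the published weight-assignment rule to full-model ORs.

    Conditions with OR <= ``exclusion_or`` are excluded (boundary
    inclusive, as the rule is printed) unless listed in ``overrides``; the
    rest get weight = OR rounded to the nearest natural number. ``over70_ors``
    supplies the separate over-70 model's ORs for age-restricted conditions.
    Deterministic and invariant to condition order.
    """
    rounder = _ROUNDERS[rounding]
    entries, excluded = {}, {}
    sources = [(full_ors, "main")]
    if over70_ors:
        sources.append((over70_ors, "over70"))
    for ors, source in sources:
        for cid in sorted(ors):
            or_ = float(ors[cid])
            override = cid in overrides
            if or_ <= exclusion_or and not override:
                excluded[cid] = or_
                continue
            entries[cid] = WeightEntry(
                weight=max(1, rounder(or_)),
                source_or=or_,
                source_model=source,
                override=override,
            )
    return WeightTable(entries=entries, excluded=excluded)


def derive_weights(
    results: StepwiseResults,
    exclusion_or: float = DEFAULT_EXCLUSION_OR,
    rounding: str = "half-up",
    overrides: Sequence[str] = (),
) -> WeightTable:
    """Extract condition ORs from the fitted full models and apply the rule."""
    if results.full_contextual is None:
        raise ValueError(
            "full_contextual family not fitted: "
            + str(results.errors.get("full_contextual", "missing"))
        )
    full = odds_ratios(results.full_contextual)
    full_ors = {c: full[c]["or"] for c in results.condition_ids if c in full}
    over70_ors = {}
    if results.over70_full is not None:
        o70 = odds_ratios(results.over70_full)
        for cid in results.over70_condition_ids:
            if cid in o70 and cid not in full_ors:
                over70_ors[cid] = o70[cid]["or"]
    return weights_from_ors(
        full_ors, over70_ors, exclusion_or=exclusion_or, rounding=rounding,
        overrides=overrides,
    )


def published_rule_weights() -> WeightTable:
    """Re-derive the weight table by applying the printed rule to the
    published full-model OR columns (main model; over-70 model for the
    age-restricted conditions)."""
    table = published_derivation_ors()
    main = table[table["source_model"] == "main"]
    over70 = table[table["source_model"] == "over70"]
    return weights_from_ors(
        dict(zip(main["condition_id"], main["full_contextual"])),
        dict(zip(over70["condition_id"], over70["full_contextual"])),
    )


# convenience re-export: scoring.compute_hii applied to a derived table
from .scoring import compute_hii as score_from_table  # noqa: E402,F401
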