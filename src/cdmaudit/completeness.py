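"""Provenance-stratified completeness audit.

For each condition in a concept library the audit builds a yearly cohort
(patients with a qualifying diagnosis in that calendar year), then for every
clinical concept counts the distinct cohort patients carrying at least one
matching record per year, stratified by provenance (clinician-entered /
billing / claim / derived) or encounter type.  A patient with records from
several provenance streams is counted in each stratum but once in the
concept total, so stratum percentages answer "what fraction of concept
patients would a single-provenance extract capture?".

For medication concepts the audit additionally computes the yearly percent
ratio of administration records to order records.  Clinical workflows keep
that ratio roughly stable over time, so a strong monotone drift (e.g. from
~100% down to ~25%) or extreme values (administrations >= 300% of orders, or
a concept with administrations but no orders at all) are flagged as likely
missing-record problems.
"""

from __future__ import annotations

import enum
import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    Category,
    CdmDataset,
    ConceptLibrary,
    EncounterType,
    EventDomain,
    Provenance,
)

__all__ = [
    "Stratifier",
    "DatasetIndex",
    "CohortIndex",
    "StratifiedCount",
    "RatioPoint",
    "AnomalyThresholds",
    "build_cohort",
    "concept_counts",
    "provenance_percentage",
    "admin_order_ratio",
    "detect_anomalies",
    "completeness_report",
    "CompletenessReport",
    "round_half_up_percent",
    "DEFAULT_YEARS",
]

DEFAULT_YEARS: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020, 2021)


class Stratifier(str, enum.Enum):
    PROVENANCE = "provenance"
    ENCOUNTER_TYPE = "encounter_type"
    NONE = "none"


def round_half_up_percent(numerator: int, denominator: int) -> int | None:
    """Integer percent with ties rounded up; None for a zero denominator."""
    if denominator <= 0:
        return None
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass
class CohortIndex:
    condition: str
    years: tuple[int, ...]
    members: dict[int, set[str]]

    def __post_init__(self) -> None:
        ys = list(self.years)
        if ys != sorted(ys) or any(b - a != 1 for a, b in zip(ys, ys[1:])):
            raise ValueError("years must be contiguous ascending")

    def size(self, year: int) -> int:
        return len(self.members.get(year, ()))


@dataclass
class StratifiedCount:
    condition: str
    category: Category
    concept: str
    year: int
    stratifier: Stratifier
    stratum: str  # enum value, or "all" when stratifier is none
    n_patients: int
    concept_total: int
    cohort_total: int
    pct: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_patients <= self.concept_total <= self.cohort_total):
            raise ValueError(
                "invariant 0 <= n_patients <= concept_total <= cohort_total violated "
                f"({self.n_patients}/{self.concept_total}/{self.cohort_total})"
            )
        if self.pct is not None and not (0 <= self.pct <= 100):
            raise ValueError("pct must lie in [0, 100]")


@dataclass
class RatioPoint:
    condition: str
    concept: str
    year: int
    n_admin_records: int
    n_order_records: int
    ratio_pct: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n_order_records > 0:
            expected = 100.0 * self.n_admin_records / self.n_order_records
            if self.ratio_pct is None:
                self.ratio_pct = expected
        else:
            self.ratio_pct = None
            self.flags.add("zero_orders")
        if self.n_admin_records == 0:
            self.flags.add("zero_administrations")


@dataclass(frozen=True)
class AnomalyThresholds:
    """Flagging thresholds for ratio series.

    ``drift_factor``: flag a series whose max/min defined ratio reaches this
    factor (default 2.0).  ``extreme_high_pct``/``extreme_low_pct``: flag
    individual points at or beyond these percent bounds (defaults 300 and
    10).  ``min_orders``: small-count guard — points with fewer orders are
    exempt from drift/extreme flags, except the unambiguous zero-orders-with-
    administrations pattern.
    """

    drift_factor: float = 2.0
    extreme_high_pct: float = 300.0
    extreme_low_pct: float = 10.0
    min_orders: int = 20

    def __post_init__(self) -> None:
        if self.drift_factor <= 1:
            raise ValueError("drift_factor must be > 1")
        if not (self.extreme_low_pct < 100 < self.extreme_high_pct):
            raise ValueError("need extreme_low_pct < 100 < extreme_high_pct")


# ---------------------------------------------------------------------------
# Indexing helpers (pandas frames built once per dataset)
# ---------------------------------------------------------------------------

class DatasetIndex:
    """Cached frame views of a dataset keyed by normalized code and year."""

    def __init__(self, dataset: CdmDataset):
        self.dataset = dataset
        self.events = pd.DataFrame(
            {
                "patient_id": [e.patient_id for e in dataset.events],
                "year": [e.event_date.year for e in dataset.events],
                "code": [e.code.strip().upper() for e in dataset.events],
                "domain": [e.domain.value for e in dataset.events],
                "provenance": [e.provenance.value for e in dataset.events],
                "encounter_type": [e.encounter_type.value for e in dataset.events],
            }
        )
        self.orders = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in dataset.orders],
                "year": [r.order_date.year for r in dataset.orders],
                "code": [(r.code or "").strip().upper() for r in dataset.orders],
            }
        )
        self.administrations = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in dataset.administrations],
                "year": [r.admin_date.year for r in dataset.administrations],
                "code": [(r.code or "").strip().upper() for r in dataset.administrations],
            }
        )
        self.labs = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in dataset.labs],
                "year": [r.result_date.year for r in dataset.labs],
                "code": [(r.code or "").strip().upper() for r in dataset.labs],
            }
        )


def _ensure_index(dataset: CdmDataset, index: DatasetIndex | None) -> DatasetIndex:
    return index if index is not None else DatasetIndex(dataset)


def _code_mask(series: pd.Series, codes: set[str], code_match: str) -> pd.Series:
    """Exact (default) or prefix matching of record codes against a code set.

    Prefix mode also matches records whose code extends a library code
    (hierarchical diagnosis codes, e.g. library "N18" matching "N18.3").
    """
    if code_match == "exact":
        return series.isin(codes)
    if code_match != "prefix":
        raise ValueError("code_match must be 'exact' or 'prefix'")
    if not codes:
        return pd.Series(False, index=series.index)
    return series.isin(codes) | series.str.startswith(tuple(codes))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def build_cohort(
    dataset: CdmDataset,
    library: ConceptLibrary,
    condition: str,
    years: Sequence[int] = DEFAULT_YEARS,
    membership: str = "incident",
    index: DatasetIndex | None = None,
    code_match: str = "exact",
) -> CohortIndex:
    """Yearly condition cohort from qualifying diagnosis records.

    ``incident`` (default): a patient belongs to year Y when they have at
    least one qualifying diagnosis dated in Y.  ``prevalent``: membership
    persists from the first qualifying year onward.  ``code_match='prefix'``
    additionally matches hierarchical descendants of the cohort codes.
    """
    if membership not in ("incident", "prevalent"):
        raise ValueError("membership must be 'incident' or 'prevalent'")
    codes = library.cohort_codes(condition)  # raises with available conditions
    idx = _ensure_index(dataset, index)
    ev = idx.events
    mask = (ev["domain"] == EventDomain.DIAGNOSIS.value) & _code_mask(
        ev["code"], codes, code_match
    )
    sub = ev.loc[mask, ["patient_id", "year"]]
    per_year: dict[int, set[str]] = {
        int(y): set(g["patient_id"]) for y, g in sub.groupby("year")
    }
    members: dict[int, set[str]] = {}
    running: set[str] = set()
    for y in sorted(years):
        this = per_year.get(y, set())
        if membership == "prevalent":
            running = running | this
            members[y] = set(running)
        else:
            members[y] = set(this)
    return CohortIndex(condition=condition, years=tuple(sorted(years)), members=members)


# ---------------------------------------------------------------------------
# Stratified concept counts
# ---------------------------------------------------------------------------

_STRATA_VALUES = {
    Stratifier.PROVENANCE: [p.value for p in Provenance],
    Stratifier.ENCOUNTER_TYPE: [e.value for e in EncounterType],
}

_EVENT_DOMAIN_FOR_CATEGORY = {
    Category.DIAGNOSES: EventDomain.DIAGNOSIS.value,
    Category.PROCEDURES: EventDomain.PROCEDURE.value,
}


def concept_counts(
    dataset: CdmDataset,
    cohort: CohortIndex,
    library: ConceptLibrary,
    condition: str,
    concept: str,
    stratifier: Stratifier = Stratifier.PROVENANCE,
    years: Sequence[int] | None = None,
    category: Category | None = None,
    index: DatasetIndex | None = None,
    code_match: str = "exact",
) -> list[StratifiedCount]:
    """Distinct-patient concept counts per year, optionally stratified.

    The concept total for a year counts distinct cohort patients with at
    least one matching record dated that year; a patient with records in
    several strata is counted in each stratum (strata overlap by design).
    Medication concepts pool orders and administrations; medications and labs
    support only the unstratified count (their records carry no provenance
    or encounter type).
    """
    stratifier = Stratifier(stratifier)
    category = category or library.find_category(condition, concept)
    codes = library.codes(condition, category, concept)
    years = tuple(years) if years is not None else cohort.years
    idx = _ensure_index(dataset, index)

    if category in _EVENT_DOMAIN_FOR_CATEGORY:
        ev = idx.events
        sub = ev[
            (ev["domain"] == _EVENT_DOMAIN_FOR_CATEGORY[category])
            & _code_mask(ev["code"], codes, code_match)
        ]
    else:
        if stratifier is not Stratifier.NONE:
            raise ValueError(
                f"{category.value} records carry no {stratifier.value}; "
                "use stratifier='none'"
            )
        if category is Category.MEDICATIONS:
            sub = pd.concat(
                [
                    idx.orders[idx.orders["code"].isin(codes)],
                    idx.administrations[idx.administrations["code"].isin(codes)],
                ],
                ignore_index=True,
            )
        else:
            sub = idx.labs[idx.labs["code"].isin(codes)]

    out: list[StratifiedCount] = []
    for year in years:
        pool = cohort.members.get(year, set())
        ysub = sub[(sub["year"] == year) & sub["patient_id"].isin(pool)]
        concept_patients = set(ysub["patient_id"])
        total = len(concept_patients)
        common = dict(
            condition=condition,
            category=category,
            concept=concept,
            year=year,
            concept_total=total,
            cohort_total=len(pool),
        )
        if stratifier is Stratifier.NONE:
            out.append(
                StratifiedCount(
                    stratifier=stratifier, stratum="all", n_patients=total, **common
                )
            )
        else:
            per_stratum = {
                str(s): set(g["patient_id"]) for s, g in ysub.groupby(stratifier.value)
            }
            for stratum in _STRATA_VALUES[stratifier]:
                out.append(
                    StratifiedCount(
                        stratifier=stratifier,
                        stratum=stratum,
                        n_patients=len(per_stratum.get(stratum, ())),
                        **common,
                    )
                )
    return out


def provenance_percentage(counts: Iterable[StratifiedCount]) -> list[StratifiedCount]:
    """Populate integer percentages (round half up) on stratified counts."""
    out = []
    for c in counts:
        c.pct = round_half_up_percent(c.n_patients, c.concept_total)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Administration/order ratios
# ---------------------------------------------------------------------------

def admin_order_ratio(
    dataset: CdmDataset,
    cohort: CohortIndex,
    library: ConceptLibrary,
    condition: str,
    med_concept: str,
    years: Sequence[int] | None = None,
    count_unit: str = "records",
    index: DatasetIndex | None = None,
) -> list[RatioPoint]:
    """Yearly percent ratio of administrations to orders for one concept.

    Counts records by default (``count_unit='patients'`` switches to
    distinct patients); both sides are restricted to cohort-year patients.
    """
    if count_unit not in ("records", "patients"):
        raise ValueError("count_unit must be 'records' or 'patients'")
    codes = library.codes(condition, Category.MEDICATIONS, med_concept)
    years = tuple(years) if years is not None else cohort.years
    idx = _ensure_index(dataset, index)
    orders = idx.orders[idx.orders["code"].isin(codes)]
    admins = idx.administrations[idx.administrations["code"].isin(codes)]
    out: list[RatioPoint] = []
    for year in years:
        pool = cohort.members.get(year, set())
        o = orders[(orders["year"] == year) & orders["patient_id"].isin(pool)]
        a = admins[(admins["year"] == year) & admins["patient_id"].isin(pool)]
        if count_unit == "records":
            n_o, n_a = len(o), len(a)
        else:
            n_o, n_a = o["patient_id"].nunique(), a["patient_id"].nunique()
        out.append(
            RatioPoint(
                condition=condition,
                concept=med_concept,
                year=year,
                n_admin_records=int(n_a),
                n_order_records=int(n_o),
            )
        )
    return out


def detect_anomalies(
    series: Sequence[RatioPoint],
    thresholds: AnomalyThresholds = AnomalyThresholds(),
) -> list[RatioPoint]:
    """Populate drift/extreme flags on a yearly ratio series (sorted by year).

    Points with fewer than ``min_orders`` orders are exempt from drift and
    extreme flags, with one exception: a point with zero orders but at least
    ``min_orders`` administrations is the unambiguous missing-orders pattern
    and is flagged extreme.
    """
    series = sorted(series, key=lambda p: p.year)
    eligible = [
        p for p in series if p.n_order_records >= thresholds.min_orders and p.ratio_pct is not None
    ]
    ratios = [p.ratio_pct for p in eligible]
    if ratios and min(ratios) > 0 and (max(ratios) / min(ratios)) >= thresholds.drift_factor:
        for p in series:
            p.flags.add("drift")
    for p in series:
        if p.n_order_records == 0 and p.n_admin_records >= thresholds.min_orders:
            p.flags.add("extreme")
        if p.n_order_records < thresholds.min_orders or p.ratio_pct is None:
            continue
        if p.ratio_pct >= thresholds.extreme_high_pct or p.ratio_pct <= thresholds.extreme_low_pct:
            p.flags.add("extreme")
    return series


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------

@dataclass
class CompletenessReport:
    partner_label: str
    years: tuple[int, ...]
    cohorts: dict[str, CohortIndex]
    counts: list[StratifiedCount]
    ratio_series: dict[tuple[str, str], list[RatioPoint]]  # (condition, concept)

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": c.condition,
                "category": c.category.value,
                "concept": c.concept,
                "year": c.year,
                "stratifier": c.stratifier.value,
                "stratum": c.stratum,
                "n_patients": c.n_patients,
                "concept_total": c.concept_total,
                "cohort_total": c.cohort_total,
                "pct": c.pct if c.pct is not None else "",
            }
            for c in self.counts
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "condition", "category", "concept", "year", "stratifier",
                "stratum", "n_patients", "concept_total", "cohort_total", "pct",
            ],
        )

    def ratio_frame(self) -> pd.DataFrame:
        rows = []
        for (condition, concept), series in self.ratio_series.items():
            for p in series:
                rows.append(
                    {
                        "condition": condition,
                        "concept": concept,
                        "year": p.year,
                        "n_admin_records": p.n_admin_records,
                        "n_order_records": p.n_order_records,
                        "ratio_pct": "" if p.ratio_pct is None else p.ratio_pct,
                        "flags": ";".join(sorted(p.flags)),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "condition", "concept", "year", "n_admin_records",
                "n_order_records", "ratio_pct", "flags",
            ],
        )

    def flagged_concepts(self) -> dict[tuple[str, str], set[str]]:
        out: dict[tuple[str, str], set[str]] = {}
        for key, series in self.ratio_series.items():
            flags: set[str] = set()
            for p in series:
                flags |= p.flags
            if flags:
                out[key] = flags
        return out

    def summary(self) -> dict:
        return {
            "partner_label": self.partner_label,
            "years": list(self.years),
            "conditions": {
                cond: {str(y): cohort.size(y) for y in self.years}
                for cond, cohort in self.cohorts.items()
            },
            "n_count_rows": len(self.counts),
            "flagged_concepts": {
                f"{cond}/{concept}": sorted(flags)
                for (cond, concept), flags in self.flagged_concepts().items()
            },
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts_frame().to_csv(outdir / "stratified_counts.csv", index=False)
        self.ratio_frame().to_csv(outdir / "ratio_series.csv", index=False)
        with open(outdir / "completeness_summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)


def completeness_report(
    dataset: CdmDataset,
    library: ConceptLibrary,
    years: Sequence[int] = DEFAULT_YEARS,
    thresholds: AnomalyThresholds = AnomalyThresholds(),
    stratifiers: Sequence[Stratifier] = (Stratifier.PROVENANCE, Stratifier.ENCOUNTER_TYPE),
    membership: str = "incident",
) -> CompletenessReport:
    """Run the completeness audit for every condition/category/concept."""
    index = DatasetIndex(dataset)
    cohorts: dict[str, CohortIndex] = {}
    all_counts: list[StratifiedCount] = []
    ratio_series: dict[tuple[str, str], list[RatioPoint]] = {}
    for condition in library.conditions():
        cohort = build_cohort(
            dataset, library, condition, years=years, membership=membership, index=index
        )
        cohorts[condition] = cohort
        for category in library.categories(condition):
            for concept in library.concepts(condition, category):
                if category in (Category.DIAGNOSES, Category.PROCEDURES):
                    use = [s for s in stratifiers if s is not Stratifier.NONE] or [
                        Stratifier.NONE
                    ]
                    use = list(use) + [Stratifier.NONE]
                else:
                    use = [Stratifier.NONE]
                for stratifier in use:
                    counts = concept_counts(
                        dataset, cohort, library, condition, concept,
                        stratifier=stratifier, years=years, category=category,
                        index=index,
                    )
                    all_counts.extend(provenance_percentage(counts))
                if category is Category.MEDICATIONS:
                    series = admin_order_ratio(
                        dataset, cohort, library, condition, concept,
                        years=years, index=index,
                    )
                    ratio_series[(condition, concept)] = detect_anomalies(
                        series, thresholds
                    )
    return CompletenessReport(
        partner_label=dataset.partner_label,
        years=tuple(sorted(years)),
        cohorts=cohorts,
        counts=all_counts,
        ratio_series=ratio_series,
    )
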