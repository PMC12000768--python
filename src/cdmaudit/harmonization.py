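"""Terminology-harmonization audit.

Given a CDM dataset and a reference terminology, the audit:

1. selects the top-N raw names by record volume in each domain (medication
   orders, medication administrations, laboratory results);
2. computes bidirectional mapping-cardinality statistics (distinct codes per
   raw name and distinct raw names per code; min/median/max) — the working
   assumption for well-harmonized data is a median of 1 in both directions;
3. enumerates the name/code crosswalk, flagging multi-mapped and null-mapped
   pairs;
4. grades every suspicious pair on a severity scale (critical / major /
   moderate / minor / unknown) by comparing the ingredients of the assigned
   drug code with the tokens of the medication name, and the component of
   the lab code with the raw laboratory name;
5. attaches record/patient impact counts measured against the full
   (pre-top-N) domain tables.

Severity grading is a first-match-wins cascade, so each crosswalk pair
yields at most one finding and impact counts stay disjoint.
"""

from __future__ import annotations

import enum
import json
import statistics
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CdmDataset,
    MethodFlag,
    TermGranularity,
    TerminologyReference,
    TermSystem,
)
from .names import NameNormalizer, NormalizedName, normalize_name

__all__ = [
    "RecordDomain",
    "Direction",
    "Severity",
    "IssueType",
    "SEVERITIES_BY_ISSUE",
    "HarmonizationConfig",
    "CardinalityStats",
    "TopNameSelection",
    "CrosswalkEntry",
    "CrosswalkContext",
    "DiscrepancyFinding",
    "Disposition",
    "HarmonizationReport",
    "select_top_names",
    "mapping_cardinality",
    "enumerate_crosswalk",
    "classify_discrepancy",
    "result_distribution_outlier",
    "impact_counts",
    "harmonization_report",
    "normalize_name",
]


class RecordDomain(str, enum.Enum):
    ORDERS = "orders"
    ADMINISTRATIONS = "administrations"
    LABS = "labs"


class Direction(str, enum.Enum):
    CODES_PER_NAME = "codes_per_name"
    NAMES_PER_CODE = "names_per_code"


class Severity(str, enum.Enum):
    CRITICAL = "critical"
    MAJOR = "major"
    MODERATE = "moderate"
    MINOR = "minor"
    UNKNOWN = "unknown"


class IssueType(str, enum.Enum):
    LAB_TEST_MISMATCH = "lab_test_mismatch"
    INGREDIENT_MISMATCH = "ingredient_mismatch"  # drug name/code ingredient disjoint
    MULTI_INGREDIENT_TO_SINGLE_CODE = "multi_ingredient_to_single_code"
    SINGLE_INGREDIENT_TO_MULTI_CODE = "single_ingredient_to_multi_code"
    NULL_CODE = "null_code"
    INGREDIENT_LEVEL_CODE = "ingredient_level_code"
    OVERGRANULAR_CODE = "overgranular_code"
    GENERIC_NAME_BRAND_CODE = "generic_name_brand_code"
    BRAND_NAME_GENERIC_CODE = "brand_name_generic_code"
    SHARED_CODE_DIFFERENT_COMPONENTS = "shared_code_different_components"
    POC_CLINICAL_SHARED_CODE = "poc_clinical_shared_code"
    RESULT_DISTRIBUTION_OUTLIER = "result_distribution_outlier"
    UNINFORMATIVE_NAME = "uninformative_name"
    MIXTURE_MULTI_CODE = "mixture_multi_code"


#: Allowed severities per issue class.  shared_code_different_components is
#: critical when paired result conventions (count vs percent) conflict and
#: moderate otherwise; every other class maps to a single severity.
SEVERITIES_BY_ISSUE: dict[IssueType, frozenset[Severity]] = {
    IssueType.LAB_TEST_MISMATCH: frozenset({Severity.CRITICAL}),
    IssueType.INGREDIENT_MISMATCH: frozenset({Severity.CRITICAL}),
    IssueType.MULTI_INGREDIENT_TO_SINGLE_CODE: frozenset({Severity.CRITICAL}),
    IssueType.SINGLE_INGREDIENT_TO_MULTI_CODE: frozenset({Severity.CRITICAL}),
    IssueType.NULL_CODE: frozenset({Severity.CRITICAL}),
    IssueType.INGREDIENT_LEVEL_CODE: frozenset({Severity.MAJOR}),
    IssueType.OVERGRANULAR_CODE: frozenset({Severity.MAJOR}),
    IssueType.GENERIC_NAME_BRAND_CODE: frozenset({Severity.MODERATE}),
    IssueType.BRAND_NAME_GENERIC_CODE: frozenset({Severity.MODERATE}),
    IssueType.SHARED_CODE_DIFFERENT_COMPONENTS: frozenset(
        {Severity.CRITICAL, Severity.MODERATE}
    ),
    IssueType.POC_CLINICAL_SHARED_CODE: frozenset({Severity.MINOR}),
    IssueType.RESULT_DISTRIBUTION_OUTLIER: frozenset({Severity.MINOR}),
    IssueType.UNINFORMATIVE_NAME: frozenset({Severity.UNKNOWN}),
    IssueType.MIXTURE_MULTI_CODE: frozenset({Severity.MINOR}),
}


@dataclass(frozen=True)
class HarmonizationConfig:
    """Tunables for the audit.

    ``uninformative_substrings`` are matched against the normalized name key;
    a name is also graded uninformative when it is all digits or shares no
    token with either the ingredient/component vocabulary or the code
    description.  ``poc_markers`` identify point-of-care test names.
    """

    top_n: int = 200
    uninformative_substrings: tuple[str, ...] = ("template", "non formulary", "zz")
    poc_markers: frozenset[str] = frozenset({"poct", "poc", "meter", "wb", "istat"})
    convention_tokens: frozenset[str] = frozenset({"abs", "absolute", "pct", "percent"})
    lab_filler_tokens: frozenset[str] = frozenset(
        {"lvl", "level", "random", "s", "bld", "blood", "auto", "automated", "in", "by"}
    )
    outlier_min_n: int = 50
    outlier_iqr_factor: float = 1.5


DEFAULT_CONFIG = HarmonizationConfig()


@dataclass
class CardinalityStats:
    direction: Direction
    domain: RecordDomain
    median: float
    minimum: int
    maximum: int
    per_key: dict[str, int]

    def __post_init__(self) -> None:
        if not (self.minimum <= self.median <= self.maximum):
            raise ValueError("cardinality stats violate min <= median <= max")


@dataclass
class TopNameSelection:
    """Output of top-N-by-volume selection for one domain."""

    domain: RecordDomain
    names: list[str]  # representative original spellings, rank order
    name_keys: list[str]
    records: list  # every record whose raw name is one of the selected names
    counts: dict[str, int]  # name_key -> record count (all ranked names)
    n_null_name_records: int  # records whose raw name is null/empty


@dataclass
class CrosswalkEntry:
    """One distinct (raw name, code) pair, including (name, null)."""

    domain: RecordDomain
    raw_name: str
    name_key: str
    code: str | None
    n_records: int
    n_patients: int
    multi_code: bool = False  # this name maps to >1 distinct non-null codes
    multi_name: bool = False  # this code maps to >1 distinct names
    fraction_of_domain_records: float = 0.0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.n_patients > self.n_records:
            raise ValueError("crosswalk entry needs 1 <= n_patients <= n_records")

    @property
    def null_mapped(self) -> bool:
        return self.code is None


@dataclass
class DiscrepancyFinding:
    entry: CrosswalkEntry
    issue_type: IssueType
    severity: Severity
    rationale: str
    n_records: int = 0
    n_patients: int = 0
    fraction_of_domain_records: float = 0.0

    def __post_init__(self) -> None:
        allowed = SEVERITIES_BY_ISSUE[self.issue_type]
        if self.severity not in allowed:
            raise ValueError(
                f"severity {self.severity.value} not allowed for "
                f"{self.issue_type.value} (allowed: {sorted(s.value for s in allowed)})"
            )
        if not (0.0 <= self.fraction_of_domain_records <= 1.0):
            raise ValueError("fraction_of_domain_records must lie in [0, 1]")


@dataclass
class Disposition:
    """Explicit non-finding outcome for a crosswalk entry."""

    entry: CrosswalkEntry
    status: str  # "ok" or "unassessable"
    note: str = ""


@dataclass
class HarmonizationReport:
    partner_label: str
    cardinality: dict[tuple[Direction, RecordDomain], CardinalityStats]
    findings: list[DiscrepancyFinding]
    dispositions: list[Disposition]
    totals: dict[RecordDomain, dict[str, int]]
    absent_domains: list[RecordDomain] = field(default_factory=list)
    selections: dict[RecordDomain, TopNameSelection] = field(default_factory=dict)

    def findings_by_severity(self) -> dict[Severity, int]:
        out = {s: 0 for s in Severity}
        for f in self.findings:
            out[f.severity] += 1
        return out

    def max_severity(self) -> Severity | None:
        order = [Severity.CRITICAL, Severity.MAJOR, Severity.MODERATE, Severity.MINOR, Severity.UNKNOWN]
        present = {f.severity for f in self.findings}
        for s in order:
            if s in present:
                return s
        return None

    # -- serialization ------------------------------------------------------

    def cardinality_frame(self) -> pd.DataFrame:
        rows = []
        for (direction, domain), stats in self.cardinality.items():
            rows.append(
                {
                    "direction": direction.value,
                    "domain": domain.value,
                    "median": stats.median,
                    "minimum": stats.minimum,
                    "maximum": stats.maximum,
                }
            )
        return pd.DataFrame(rows, columns=["direction", "domain", "median", "minimum", "maximum"])

    def findings_frame(self) -> pd.DataFrame:
        rows = [
            {
                "domain": f.entry.domain.value,
                "raw_name": f.entry.raw_name,
                "code": f.entry.code or "",
                "issue_type": f.issue_type.value,
                "severity": f.severity.value,
                "rationale": f.rationale,
                "n_records": f.n_records,
                "n_patients": f.n_patients,
                "fraction_of_domain_records": f.fraction_of_domain_records,
            }
            for f in self.findings
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "domain", "raw_name", "code", "issue_type", "severity",
                "rationale", "n_records", "n_patients", "fraction_of_domain_records",
            ],
        )

    def crosswalk_frame(self) -> pd.DataFrame:
        rows = []
        for disp in self.dispositions:
            e = disp.entry
            rows.append(
                {
                    "domain": e.domain.value,
                    "raw_name": e.raw_name,
                    "code": e.code or "",
                    "n_records": e.n_records,
                    "n_patients": e.n_patients,
                    "multi_code": e.multi_code,
                    "multi_name": e.multi_name,
                    "null_mapped": e.null_mapped,
                    "disposition": disp.status,
                }
            )
        for f in self.findings:
            e = f.entry
            rows.append(
                {
                    "domain": e.domain.value,
                    "raw_name": e.raw_name,
                    "code": e.code or "",
                    "n_records": e.n_records,
                    "n_patients": e.n_patients,
                    "multi_code": e.multi_code,
                    "multi_name": e.multi_name,
                    "null_mapped": e.null_mapped,
                    "disposition": f"finding:{f.issue_type.value}",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "domain", "raw_name", "code", "n_records", "n_patients",
                "multi_code", "multi_name", "null_mapped", "disposition",
            ],
        )

    def summary(self) -> dict:
        return {
            "partner_label": self.partner_label,
            "totals": {d.value: t for d, t in self.totals.items()},
            "absent_domains": [d.value for d in self.absent_domains],
            "findings_by_severity": {
                s.value: n for s, n in self.findings_by_severity().items()
            },
            "n_findings": len(self.findings),
            "n_dispositions": len(self.dispositions),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cardinality_frame().to_csv(outdir / "cardinality.csv", index=False)
        self.findings_frame().to_csv(outdir / "findings.csv", index=False)
        self.crosswalk_frame().to_csv(outdir / "crosswalk.csv", index=False)
        with open(outdir / "harmonization_summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)


# ---------------------------------------------------------------------------
# Top-N selection
# ---------------------------------------------------------------------------

def select_top_names(
    records: Sequence,
    n: int = 200,
    domain: RecordDomain = RecordDomain.ORDERS,
    normalizer: NameNormalizer | None = None,
) -> TopNameSelection:
    """Rank raw names by record volume and keep the top ``n``.

    Ranking is by descending record count with ties broken by ascending
    lexicographic (representative original) name, so the output is
    deterministic regardless of record order.  Null/empty raw names are
    excluded from ranking but counted separately.  All records whose raw name
    is among the selected names are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    norm = normalizer or normalize_name
    counts: dict[str, int] = defaultdict(int)
    representative: dict[str, str] = {}
    n_null = 0
    keyed: list[tuple[str, object]] = []
    for r in records:
        nn = norm(r.raw_name)
        if nn.is_empty:
            n_null += 1
            keyed.append(("", r))
            continue
        counts[nn.key] += 1
        rep = representative.get(nn.key)
        if rep is None or nn.original < rep:
            representative[nn.key] = nn.original
        keyed.append((nn.key, r))
    ranked = sorted(counts, key=lambda k: (-counts[k], representative[k]))
    selected_keys = ranked[: min(n, len(ranked))]
    selected_set = set(selected_keys)
    return TopNameSelection(
        domain=domain,
        names=[representative[k] for k in selected_keys],
        name_keys=selected_keys,
        records=[r for key, r in keyed if key in selected_set],
        counts=dict(counts),
        n_null_name_records=n_null,
    )


# ---------------------------------------------------------------------------
# Cardinality
# ---------------------------------------------------------------------------

def mapping_cardinality(
    records: Sequence,
    direction: Direction,
    domain: RecordDomain = RecordDomain.ORDERS,
    normalizer: NameNormalizer | None = None,
) -> CardinalityStats:
    """Min/median/max of distinct counterparts per key.

    ``codes_per_name``: keys are distinct raw names; counts are distinct
    non-null codes (a name mapped only to null codes counts 0 — this is how
    a minimum of 0 arises).  ``names_per_code``: keys are distinct non-null
    codes; counts are distinct raw names.
    """
    direction = Direction(direction)
    if not records:
        raise ValueError("no records to summarize")
    norm = normalizer or normalize_name
    pairs: set[tuple[str, str | None]] = set()
    names: set[str] = set()
    for r in records:
        key = norm(r.raw_name).key
        if not key:
            continue
        names.add(key)
        pairs.add((key, r.code))
    per_key: dict[str, set] = defaultdict(set)
    if direction is Direction.CODES_PER_NAME:
        for name in names:
            per_key[name]  # ensure zero-count names appear
        for name, code in pairs:
            if code is not None:
                per_key[name].add(code)
    else:
        for name, code in pairs:
            if code is not None:
                per_key[code].add(name)
    if not per_key:
        raise ValueError("no keys to summarize (all codes null?)")
    counts = {k: len(v) for k, v in per_key.items()}
    values = list(counts.values())
    return CardinalityStats(
        direction=direction,
        domain=domain,
        median=float(statistics.median(values)),
        minimum=int(min(values)),
        maximum=int(max(values)),
        per_key=counts,
    )


# ---------------------------------------------------------------------------
# Crosswalk enumeration
# ---------------------------------------------------------------------------

def enumerate_crosswalk(
    records: Sequence,
    domain: RecordDomain = RecordDomain.ORDERS,
    normalizer: NameNormalizer | None = None,
) -> list[CrosswalkEntry]:
    """One entry per distinct (raw name, code) pair, including null codes."""
    norm = normalizer or normalize_name
    n_records: dict[tuple[str, str | None], int] = defaultdict(int)
    patients: dict[tuple[str, str | None], set[str]] = defaultdict(set)
    representative: dict[str, str] = {}
    for r in records:
        nn = norm(r.raw_name)
        if nn.is_empty:
            continue
        pair = (nn.key, r.code)
        n_records[pair] += 1
        patients[pair].add(r.patient_id)
        rep = representative.get(nn.key)
        if rep is None or nn.original < rep:
            representative[nn.key] = nn.original
    codes_by_name: dict[str, set[str]] = defaultdict(set)
    names_by_code: dict[str, set[str]] = defaultdict(set)
    for name, code in n_records:
        if code is not None:
            codes_by_name[name].add(code)
            names_by_code[code].add(name)
    entries = [
        CrosswalkEntry(
            domain=domain,
            raw_name=representative[name],
            name_key=name,
            code=code,
            n_records=n_records[(name, code)],
            n_patients=len(patients[(name, code)]),
            multi_code=len(codes_by_name.get(name, ())) > 1,
            multi_name=code is not None and len(names_by_code[code]) > 1,
        )
        for (name, code) in sorted(
            n_records, key=lambda p: (p[0], p[1] if p[1] is not None else "")
        )
    ]
    return entries


class CrosswalkContext:
    """Sibling lookups over one domain's crosswalk (for context-aware rules)."""

    def __init__(self, entries: Iterable[CrosswalkEntry]):
        self.by_name: dict[str, list[CrosswalkEntry]] = defaultdict(list)
        self.by_code: dict[str, list[CrosswalkEntry]] = defaultdict(list)
        for e in entries:
            self.by_name[e.name_key].append(e)
            if e.code is not None:
                self.by_code[e.code].append(e)

    def codes_for_name(self, name_key: str) -> list[str]:
        return sorted({e.code for e in self.by_name.get(name_key, []) if e.code is not None})

    def names_for_code(self, code: str) -> list[str]:
        return sorted({e.name_key for e in self.by_code.get(code, [])})


# ---------------------------------------------------------------------------
# Severity classification
# ---------------------------------------------------------------------------

def _fuzzy_overlap(a: Iterable[str], b: Iterable[str]) -> bool:
    """Token-set overlap tolerant of truncated raw names.

    Raw names routinely abbreviate ("EOS" for eosinophils, "CREAT" for
    creatinine), so a token matches when it equals another or is a prefix of
    it (at least 3 characters, to keep short fragments from matching
    everything).
    """
    b = set(b)
    for t in a:
        if t in b:
            return True
        if len(t) >= 3 and any(u.startswith(t) for u in b):
            return True
        if any(len(u) >= 3 and t.startswith(u) for u in b):
            return True
    return False


def _has_poc_marker(nn: NormalizedName, config: HarmonizationConfig) -> bool:
    if nn.all_tokens & config.poc_markers:
        return True
    return "point of care" in nn.key


def _is_pattern_uninformative(nn: NormalizedName, config: HarmonizationConfig) -> bool:
    if not nn.key:
        return False
    if nn.key.replace(" ", "").isdigit():
        return True
    for sub in config.uninformative_substrings:
        if sub in nn.key:
            return True
    return False


def _lab_component_tokens(
    nn: NormalizedName, config: HarmonizationConfig
) -> frozenset[str]:
    """Name tokens that plausibly carry the measured component."""
    return frozenset(
        t
        for t in nn.all_tokens
        if t not in config.lab_filler_tokens
        and t not in config.convention_tokens
        and t not in config.poc_markers
        and not t.isdigit()
    )


def classify_discrepancy(
    entry: CrosswalkEntry,
    ref: TerminologyReference,
    context: CrosswalkContext,
    config: HarmonizationConfig = DEFAULT_CONFIG,
    normalizer: NameNormalizer | None = None,
) -> DiscrepancyFinding | Disposition:
    """Grade one crosswalk pair.  First matching rule wins.

    Order: null code -> uninformative (pattern) -> unknown code
    (unassessable) -> uninformative (no token signal) -> domain-specific
    fidelity cascade (drug ingredient rules, then granularity/brand rules;
    lab component rules, then point-of-care and shared-code rules).
    """
    norm = normalizer or normalize_name
    nn = norm(entry.raw_name)

    def finding(issue: IssueType, severity: Severity, rationale: str) -> DiscrepancyFinding:
        return DiscrepancyFinding(entry=entry, issue_type=issue, severity=severity, rationale=rationale)

    if entry.code is None:
        return finding(
            IssueType.NULL_CODE,
            Severity.CRITICAL,
            "raw name carries no code; records are invisible to code-based queries",
        )
    if _is_pattern_uninformative(nn, config):
        return finding(
            IssueType.UNINFORMATIVE_NAME,
            Severity.UNKNOWN,
            "raw name matches an uninformative pattern (template/placeholder/integer); "
            "mapping cannot be assessed",
        )
    concept = ref.get(entry.code)
    if concept is None:
        return Disposition(
            entry,
            "unassessable",
            f"code {entry.code} absent from terminology reference",
        )
    desc = norm(concept.description)

    is_drug = concept.system is TermSystem.DRUG
    if is_drug:
        vocab_overlap = bool(nn.ingredient_tokens & ref.ingredient_vocabulary)
    else:
        vocab_overlap = _fuzzy_overlap(nn.ingredient_tokens, ref.component_vocabulary)
    if not vocab_overlap and not _fuzzy_overlap(nn.all_tokens, desc.all_tokens):
        return finding(
            IssueType.UNINFORMATIVE_NAME,
            Severity.UNKNOWN,
            "raw name shares no token with the reference vocabulary or the code "
            "description; mapping cannot be assessed",
        )

    if is_drug:
        return _classify_drug(entry, nn, concept, ref, context, config, norm, finding)
    return _classify_lab(entry, nn, concept, ref, context, config, norm, finding)


def _classify_drug(entry, nn, concept, ref, context, config, norm, finding):
    name_ings = nn.ingredient_tokens & ref.ingredient_vocabulary
    code_ings: set[str] = set()
    for ing in concept.ingredients:
        code_ings.update(norm(ing).all_tokens)

    # Mixture shadowing: one raw name mapped to several single-ingredient
    # codes, each ingredient present in the name -> informational split of a
    # mixture order across per-ingredient records, not a mapping error.
    if entry.multi_code:
        siblings = [ref.get(c) for c in context.codes_for_name(entry.name_key)]
        if siblings and all(s is not None and len(s.ingredients) == 1 for s in siblings):
            covered = all(
                norm(s.ingredients[0]).all_tokens & nn.all_tokens for s in siblings
            )
            if covered:
                return finding(
                    IssueType.MIXTURE_MULTI_CODE,
                    Severity.MINOR,
                    "mixture medication represented as one record per ingredient-level "
                    "code; informational, verify all ingredient records are populated",
                )

    n_code_ings = len(concept.ingredients)
    if len(name_ings) >= 2 and n_code_ings == 1:
        return finding(
            IssueType.MULTI_INGREDIENT_TO_SINGLE_CODE,
            Severity.CRITICAL,
            f"name lists multiple ingredients {sorted(name_ings)} but code "
            f"{concept.code} represents a single ingredient",
        )
    if len(name_ings) == 1 and n_code_ings >= 2:
        return finding(
            IssueType.SINGLE_INGREDIENT_TO_MULTI_CODE,
            Severity.CRITICAL,
            f"single-ingredient name mapped to multi-ingredient code "
            f"{concept.code} ({', '.join(concept.ingredients)})",
        )
    if name_ings and code_ings and not (name_ings & code_ings):
        return finding(
            IssueType.INGREDIENT_MISMATCH,
            Severity.CRITICAL,
            f"no ingredient overlap between name and code description "
            f"{concept.description!r}; records do not represent exposure to the "
            "named medication",
        )
    if concept.term_granularity is TermGranularity.INGREDIENT and nn.attribute_tokens:
        return finding(
            IssueType.INGREDIENT_LEVEL_CODE,
            Severity.MAJOR,
            "name carries strength/form attributes but the code is ingredient-level; "
            "form-restricted analyses may drop these records",
        )
    if (
        concept.term_granularity in (TermGranularity.CLINICAL_DRUG, TermGranularity.BRANDED_DRUG)
        and not nn.attribute_tokens
    ):
        return finding(
            IssueType.OVERGRANULAR_CODE,
            Severity.MAJOR,
            "code is more granular (strength/form/brand) than the bare name supports; "
            "records may be wrongly included in form-specific analyses",
        )
    if concept.term_granularity is TermGranularity.BRANDED_DRUG:
        brand_tokens = norm(concept.brand or "").all_tokens
        if not brand_tokens or not (brand_tokens & nn.all_tokens):
            return finding(
                IssueType.GENERIC_NAME_BRAND_CODE,
                Severity.MODERATE,
                f"generic name mapped to branded code {concept.code} "
                f"({concept.brand or concept.description}); brand-specific studies "
                "will include extra records",
            )
    if (
        concept.term_granularity is not TermGranularity.BRANDED_DRUG
        and nn.ingredient_tokens & ref.brand_vocabulary
    ):
        return finding(
            IssueType.BRAND_NAME_GENERIC_CODE,
            Severity.MODERATE,
            "brand-carrying name mapped to a generic-level code; brand-specific "
            "studies will miss these records",
        )
    return Disposition(entry, "ok", "no discrepancy")


def _classify_lab(entry, nn, concept, ref, context, config, norm, finding):
    comp = norm(concept.component or concept.description)
    name_comp = _lab_component_tokens(nn, config)
    desc_tokens = comp.all_tokens | norm(concept.description).all_tokens
    if name_comp and not _fuzzy_overlap(name_comp, desc_tokens):
        return finding(
            IssueType.LAB_TEST_MISMATCH,
            Severity.CRITICAL,
            f"no component overlap between raw name and code description "
            f"{concept.description!r}; the code does not represent this test",
        )
    sibling_keys = context.names_for_code(entry.code) if entry.code else []
    siblings = [norm_key for norm_key in sibling_keys if norm_key != entry.name_key]
    if _has_poc_marker(nn, config):
        shared_with_non_poc = any(
            not _has_poc_marker(norm(k), config) for k in siblings
        )
        if concept.method_flag is MethodFlag.CLINICAL_LAB or shared_with_non_poc:
            return finding(
                IssueType.POC_CLINICAL_SHARED_CODE,
                Severity.MINOR,
                "point-of-care test shares a clinical-laboratory code; "
                "method-specific analyses are not possible",
            )
    if entry.multi_name and siblings:
        own_conv = nn.all_tokens & config.convention_tokens
        convention_sets = {frozenset(own_conv)}
        for k in siblings:
            convention_sets.add(frozenset(norm(k).all_tokens & config.convention_tokens))
        convention_sets.discard(frozenset())
        if len(convention_sets) >= 2:
            return finding(
                IssueType.SHARED_CODE_DIFFERENT_COMPONENTS,
                Severity.CRITICAL,
                "names reporting different result conventions (count vs percent) "
                "share one code; one convention must be mapped incorrectly",
            )
        own_comp = name_comp
        for k in siblings:
            if _lab_component_tokens(norm(k), config) != own_comp:
                return finding(
                    IssueType.SHARED_CODE_DIFFERENT_COMPONENTS,
                    Severity.MODERATE,
                    "names with differing component tokens share one code; results "
                    "should not necessarily be grouped together",
                )
    return Disposition(entry, "ok", "no discrepancy")


# ---------------------------------------------------------------------------
# Result-distribution outlier screen (labs)
# ---------------------------------------------------------------------------

def result_distribution_outlier(
    lab_records: Sequence,
    min_n: int = 50,
    iqr_factor: float = 1.5,
    normalizer: NameNormalizer | None = None,
) -> list[tuple[str, str, float, tuple[float, float]]]:
    """Flag raw names whose result distribution is an outlier under a shared code.

    For each code shared by >=2 raw names, a name with at least ``min_n``
    numeric results is flagged when its median lies outside the pooled
    Tukey fence (Q1 - f*IQR, Q3 + f*IQR) of all *other* names' results under
    that code.  Returns tuples of (code, raw_name, median, fence).
    """
    norm = normalizer or normalize_name
    by_code: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    representative: dict[str, str] = {}
    for r in lab_records:
        if r.code is None or r.numeric_result is None:
            continue
        nn = norm(r.raw_name)
        if nn.is_empty:
            continue
        by_code[r.code][nn.key].append(float(r.numeric_result))
        rep = representative.get(nn.key)
        if rep is None or nn.original < rep:
            representative[nn.key] = nn.original
    flagged = []
    for code in sorted(by_code):
        groups = by_code[code]
        if len(groups) < 2:
            continue
        for name in sorted(groups):
            values = groups[name]
            if len(values) < min_n:
                continue
            others = [v for other, vs in groups.items() if other != name for v in vs]
            if len(others) < min_n:
                continue
            q1, q3 = np.percentile(others, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
            med = float(np.median(values))
            if med < lo or med > hi:
                flagged.append((code, representative[name], med, (float(lo), float(hi))))
    return flagged


# ---------------------------------------------------------------------------
# Impact counts
# ---------------------------------------------------------------------------

def impact_counts(
    finding: DiscrepancyFinding,
    domain_records: Sequence,
    normalizer: NameNormalizer | None = None,
    _pair_counts: Mapping[tuple[str, str | None], tuple[int, int]] | None = None,
) -> DiscrepancyFinding:
    """Populate record/patient impact from the full (pre-top-N) domain table."""
    norm = normalizer or normalize_name
    pair = (finding.entry.name_key, finding.entry.code)
    if _pair_counts is not None:
        n_rec, n_pat = _pair_counts.get(pair, (0, 0))
    else:
        n_rec = 0
        pats: set[str] = set()
        for r in domain_records:
            if norm(r.raw_name).key == pair[0] and r.code == pair[1]:
                n_rec += 1
                pats.add(r.patient_id)
        n_pat = len(pats)
    total = len(domain_records)
    finding.n_records = n_rec
    finding.n_patients = n_pat
    finding.fraction_of_domain_records = (n_rec / total) if total else 0.0
    finding.entry.fraction_of_domain_records = finding.fraction_of_domain_records
    return finding


def _pair_count_index(records: Sequence, norm) -> dict[tuple[str, str | None], tuple[int, int]]:
    n_rec: dict[tuple[str, str | None], int] = defaultdict(int)
    pats: dict[tuple[str, str | None], set[str]] = defaultdict(set)
    for r in records:
        key = norm(r.raw_name).key
        if not key:
            continue
        pair = (key, r.code)
        n_rec[pair] += 1
        pats[pair].add(r.patient_id)
    return {p: (n_rec[p], len(pats[p])) for p in n_rec}


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------

def harmonization_report(
    dataset: CdmDataset,
    ref: TerminologyReference,
    n: int = 200,
    config: HarmonizationConfig = DEFAULT_CONFIG,
    normalizer: NameNormalizer | None = None,
    domains: Sequence[RecordDomain] | None = None,
) -> HarmonizationReport:
    """Run the harmonization audit over orders, administrations and labs
    (or the subset given in ``domains``)."""
    norm = normalizer or normalize_name
    wanted = tuple(RecordDomain(d) for d in domains) if domains else tuple(RecordDomain)
    cardinality: dict[tuple[Direction, RecordDomain], CardinalityStats] = {}
    findings: list[DiscrepancyFinding] = []
    dispositions: list[Disposition] = []
    totals: dict[RecordDomain, dict[str, int]] = {}
    absent: list[RecordDomain] = []
    selections: dict[RecordDomain, TopNameSelection] = {}

    domain_records = {
        RecordDomain.ORDERS: dataset.orders,
        RecordDomain.ADMINISTRATIONS: dataset.administrations,
        RecordDomain.LABS: dataset.labs,
    }
    for domain, records in domain_records.items():
        if domain not in wanted:
            continue
        totals[domain] = {
            "n_records": len(records),
            "n_patients": len({r.patient_id for r in records}),
        }
        if not records:
            absent.append(domain)
            continue
        selection = select_top_names(records, n=n, domain=domain, normalizer=norm)
        selections[domain] = selection
        for direction in Direction:
            cardinality[(direction, domain)] = mapping_cardinality(
                selection.records, direction, domain=domain, normalizer=norm
            )
        entries = enumerate_crosswalk(selection.records, domain=domain, normalizer=norm)
        context = CrosswalkContext(entries)
        pair_counts = _pair_count_index(records, norm)
        for entry in entries:
            outcome = classify_discrepancy(entry, ref, context, config=config, normalizer=norm)
            if isinstance(outcome, DiscrepancyFinding):
                impact_counts(outcome, records, normalizer=norm, _pair_counts=pair_counts)
                findings.append(outcome)
            else:
                dispositions.append(outcome)
        if domain is RecordDomain.LABS:
            entry_lookup = {(e.name_key, e.code): e for e in entries}
            for code, raw_name, med, fence in result_distribution_outlier(
                selection.records,
                min_n=config.outlier_min_n,
                iqr_factor=config.outlier_iqr_factor,
                normalizer=norm,
            ):
                entry = entry_lookup.get((norm(raw_name).key, code))
                if entry is None:
                    continue
                f = DiscrepancyFinding(
                    entry=entry,
                    issue_type=IssueType.RESULT_DISTRIBUTION_OUTLIER,
                    severity=Severity.MINOR,
                    rationale=(
                        f"median result {med:g} falls outside the pooled fence "
                        f"({fence[0]:g}, {fence[1]:g}) of other names under this code"
                    ),
                )
                impact_counts(f, records, normalizer=norm, _pair_counts=pair_counts)
                findings.append(f)
    return HarmonizationReport(
        partner_label=dataset.partner_label,
        cardinality=cardinality,
        findings=findings,
        dispositions=dispositions,
        totals=totals,
        absent_domains=absent,
        selections=selections,
    )
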