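"""Domain types for a PCORnet-style common data model extract.

The audits in this package operate on five record collections — laboratory
results, medication orders (prescribing), medication administrations, and
coded clinical events (diagnoses and procedures) — plus two reference
structures: a toy terminology (LOINC-like lab codes, RxNorm-like drug codes)
and a declarative concept library (condition -> category -> concept -> codes).

All types are plain dataclasses; record collections are ordinary lists so a
dataset can be built programmatically, read from delimited files, or emitted
by the synthetic generator interchangeably.
"""

from __future__ import annotations

import datetime as _dt
import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Provenance",
    "EncounterType",
    "EventDomain",
    "TableKind",
    "Category",
    "TermSystem",
    "MethodFlag",
    "TermGranularity",
    "LabRecord",
    "MedOrderRecord",
    "MedAdminRecord",
    "CodedEventRecord",
    "CdmDataset",
    "TerminologyConcept",
    "TerminologyReference",
    "ConceptLibrary",
    "coerce_provenance",
    "coerce_encounter_type",
    "LAB_CODE_RE",
    "DRUG_CODE_RE",
]

#: LOINC-style lab code: digits, hyphen, single check digit (e.g. "2345-7").
LAB_CODE_RE = re.compile(r"^\d+-\d$")
#: RxNorm-style drug code: digits only.
DRUG_CODE_RE = re.compile(r"^\d+$")


class Provenance(str, enum.Enum):
    """Origin of a diagnosis/procedure record within the EHR workflow."""

    ORDERED = "ordered"  # clinician-entered
    BILLING = "billing"  # generated by the health-system financial process
    CLAIM = "claim"
    DERIVED = "derived"  # e.g. NLP-derived
    UNKNOWN = "unknown"


class EncounterType(str, enum.Enum):
    OUTPATIENT = "outpatient"
    INPATIENT = "inpatient"
    EMERGENCY = "emergency"
    OTHER = "other"
    UNKNOWN = "unknown"


class EventDomain(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    PROCEDURE = "procedure"


class TableKind(str, enum.Enum):
    """Which CDM table a delimited file represents."""

    LAB = "lab"
    ORDER = "order"
    ADMINISTRATION = "administration"
    DIAGNOSIS = "diagnosis"
    PROCEDURE = "procedure"


class Category(str, enum.Enum):
    """Concept-library category."""

    DIAGNOSES = "diagnoses"
    MEDICATIONS = "medications"
    PROCEDURES = "procedures"
    LABS = "labs"


class TermSystem(str, enum.Enum):
    LAB = "lab"
    DRUG = "drug"


class MethodFlag(str, enum.Enum):
    CLINICAL_LAB = "clinical_lab"
    POINT_OF_CARE = "point_of_care"
    UNSPECIFIED = "unspecified"


class TermGranularity(str, enum.Enum):
    INGREDIENT = "ingredient"
    CLINICAL_DRUG = "clinical_drug"
    BRANDED_DRUG = "branded_drug"
    OTHER = "other"


# PCORnet-style source values for provenance (DX_ORIGIN / PX_SOURCE) and a few
# common spellings.  Anything unrecognized coerces to UNKNOWN so that counts
# stratified over the enum always partition the records.
_PROVENANCE_ALIASES: dict[str, Provenance] = {
    "OD": Provenance.ORDERED,
    "ORDER": Provenance.ORDERED,
    "ORDERED": Provenance.ORDERED,
    "CLINICIAN": Provenance.ORDERED,
    "BI": Provenance.BILLING,
    "BILLING": Provenance.BILLING,
    "BILLED": Provenance.BILLING,
    "CL": Provenance.CLAIM,
    "CLAIM": Provenance.CLAIM,
    "CLAIMS": Provenance.CLAIM,
    "DR": Provenance.DERIVED,
    "DERIVED": Provenance.DERIVED,
}

_ENCOUNTER_ALIASES: dict[str, EncounterType] = {
    "AV": EncounterType.OUTPATIENT,
    "OA": EncounterType.OUTPATIENT,
    "TH": EncounterType.OUTPATIENT,
    "OUTPATIENT": EncounterType.OUTPATIENT,
    "AMBULATORY": EncounterType.OUTPATIENT,
    "IP": EncounterType.INPATIENT,
    "EI": EncounterType.INPATIENT,
    "IS": EncounterType.INPATIENT,
    "INPATIENT": EncounterType.INPATIENT,
    "ED": EncounterType.EMERGENCY,
    "EMERGENCY": EncounterType.EMERGENCY,
    "OT": EncounterType.OTHER,
    "OTHER": EncounterType.OTHER,
}


def coerce_provenance(value: object) -> Provenance:
    """Map an arbitrary source string onto the closed provenance enum.

    Total: every input maps to exactly one enum member (unrecognized or
    missing values map to ``UNKNOWN``).
    """
    if isinstance(value, Provenance):
        return value
    if value is None:
        return Provenance.UNKNOWN
    token = str(value).strip().upper()
    try:
        return Provenance(token.lower())
    except ValueError:
        pass
    return _PROVENANCE_ALIASES.get(token, Provenance.UNKNOWN)


def coerce_encounter_type(value: object) -> EncounterType:
    """Total mapping of source encounter-type strings onto the closed enum."""
    if isinstance(value, EncounterType):
        return value
    if value is None:
        return EncounterType.UNKNOWN
    token = str(value).strip().upper()
    try:
        return EncounterType(token.lower())
    except ValueError:
        pass
    return _ENCOUNTER_ALIASES.get(token, EncounterType.UNKNOWN)


@dataclass(slots=True)
class LabRecord:
    """One laboratory result row.

    ``raw_name`` is the non-harmonized, source-system test name; ``code`` is
    the assigned LOINC-like code (or None when the record carries no code).
    """

    patient_id: str
    record_id: str
    result_date: _dt.date
    raw_name: str
    code: str | None = None
    numeric_result: float | None = None
    result_unit: str | None = None

    @property
    def date(self) -> _dt.date:
        return self.result_date


@dataclass(slots=True)
class MedOrderRecord:
    """One medication order (prescribing) row."""

    patient_id: str
    record_id: str
    order_date: _dt.date
    raw_name: str
    code: str | None = None

    @property
    def date(self) -> _dt.date:
        return self.order_date


@dataclass(slots=True)
class MedAdminRecord:
    """One medication administration row.

    Some source systems store integer-valued strings (formulary keys) in the
    raw-name field; the model permits that and the audit grades such names as
    uninformative.
    """

    patient_id: str
    record_id: str
    admin_date: _dt.date
    raw_name: str
    code: str | None = None

    @property
    def date(self) -> _dt.date:
        return self.admin_date


@dataclass(slots=True)
class CodedEventRecord:
    """A diagnosis or procedure record with provenance and encounter type."""

    patient_id: str
    record_id: str
    event_date: _dt.date
    domain: EventDomain
    code: str
    code_system: str = ""
    provenance: Provenance = Provenance.UNKNOWN
    encounter_type: EncounterType = EncounterType.UNKNOWN

    @property
    def date(self) -> _dt.date:
        return self.event_date


@dataclass
class CdmDataset:
    """All record collections for one data partner."""

    partner_label: str = ""
    labs: list[LabRecord] = field(default_factory=list)
    orders: list[MedOrderRecord] = field(default_factory=list)
    administrations: list[MedAdminRecord] = field(default_factory=list)
    events: list[CodedEventRecord] = field(default_factory=list)

    @property
    def diagnoses(self) -> list[CodedEventRecord]:
        return [e for e in self.events if e.domain is EventDomain.DIAGNOSIS]

    @property
    def procedures(self) -> list[CodedEventRecord]:
        return [e for e in self.events if e.domain is EventDomain.PROCEDURE]

    def validate(self) -> None:
        """Check record-id uniqueness within each collection."""
        for name in ("labs", "orders", "administrations", "events"):
            records = getattr(self, name)
            seen: set[str] = set()
            for r in records:
                if r.record_id in seen:
                    raise ValueError(
                        f"duplicate record_id {r.record_id!r} in {name}"
                    )
                seen.add(r.record_id)

    def counts(self) -> dict[str, int]:
        return {
            "labs": len(self.labs),
            "orders": len(self.orders),
            "administrations": len(self.administrations),
            "diagnoses": len(self.diagnoses),
            "procedures": len(self.procedures),
        }


@dataclass(frozen=True)
class TerminologyConcept:
    """One reference-terminology entry (lab or drug).

    Lab concepts carry a component/specimen/method; drug concepts carry an
    ingredient list, a granularity level (ingredient, clinical drug with
    strength/form, branded drug), and optionally a brand name.
    """

    code: str
    system: TermSystem
    description: str
    component: str | None = None
    specimen: str | None = None
    method_flag: MethodFlag = MethodFlag.UNSPECIFIED
    ingredients: tuple[str, ...] = ()
    term_granularity: TermGranularity | None = None
    brand: str | None = None

    def __post_init__(self) -> None:
        if self.system is TermSystem.LAB and self.ingredients:
            raise ValueError(f"lab concept {self.code} must not list ingredients")
        if self.system is TermSystem.DRUG:
            if self.component is not None or self.specimen is not None:
                raise ValueError(
                    f"drug concept {self.code} must not carry component/specimen"
                )
            if not self.ingredients:
                raise ValueError(f"drug concept {self.code} needs >=1 ingredient")


class TerminologyReference:
    """Code -> concept lookup plus normalized vocabularies.

    ``ingredient_vocabulary`` holds normalized drug-ingredient tokens;
    ``component_vocabulary`` the analogous lab-component tokens;
    ``brand_vocabulary`` normalized brand-name tokens.  The vocabularies feed
    the fidelity checks in :mod:`cdmaudit.harmonization`.
    """

    def __init__(self, concepts: Iterable[TerminologyConcept]):
        from .names import normalize_name

        self.concepts: dict[str, TerminologyConcept] = {}
        dups: list[str] = []
        for c in concepts:
            if c.code in self.concepts:
                dups.append(c.code)
            self.concepts[c.code] = c
        if dups:
            raise ValueError(f"duplicate terminology codes: {sorted(set(dups))}")

        self.ingredient_vocabulary: set[str] = set()
        self.component_vocabulary: set[str] = set()
        self.brand_vocabulary: set[str] = set()
        for c in self.concepts.values():
            if c.system is TermSystem.DRUG:
                for ing in c.ingredients:
                    self.ingredient_vocabulary.update(normalize_name(ing).all_tokens)
                if c.brand:
                    self.brand_vocabulary.update(normalize_name(c.brand).all_tokens)
            else:
                src = c.component or c.description
                self.component_vocabulary.update(normalize_name(src).ingredient_tokens)

    def get(self, code: str | None) -> TerminologyConcept | None:
        if code is None:
            return None
        return self.concepts.get(code)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, code: object) -> bool:
        return code in self.concepts

    def lab_concepts(self) -> list[TerminologyConcept]:
        return [c for c in self.concepts.values() if c.system is TermSystem.LAB]

    def drug_concepts(self) -> list[TerminologyConcept]:
        return [c for c in self.concepts.values() if c.system is TermSystem.DRUG]


@dataclass
class ConceptLibrary:
    """Condition -> category -> concept -> code list, plus cohort-entry codes.

    ``entries[condition][category][concept]`` is a list of
    ``(code_system, code)`` pairs; ``cohort_entry[condition]`` is the list of
    diagnosis codes that define membership in the condition cohort.
    """

    entries: dict[str, dict[Category, dict[str, list[tuple[str, str]]]]]
    cohort_entry: dict[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        for condition in self.entries:
            if not self.cohort_entry.get(condition):
                raise ValueError(
                    f"condition {condition!r} has no cohort_entry code list"
                )
            for category, concepts in self.entries[condition].items():
                if not isinstance(category, Category):
                    raise ValueError(
                        f"bad category {category!r}; allowed: "
                        f"{[c.value for c in Category]}"
                    )
                if not concepts:
                    raise ValueError(
                        f"{condition!r}/{category.value} holds no concepts"
                    )

    def conditions(self) -> list[str]:
        return list(self.entries)

    def categories(self, condition: str) -> list[Category]:
        return list(self._condition(condition))

    def concepts(self, condition: str, category: Category) -> list[str]:
        return list(self._condition(condition).get(category, {}))

    def codes(self, condition: str, category: Category, concept: str) -> set[str]:
        """Normalized (upper-cased, trimmed) code set for one concept."""
        concepts = self._condition(condition).get(category, {})
        if concept not in concepts:
            raise KeyError(
                f"concept {concept!r} not defined under {condition!r}/"
                f"{category.value}; available: {sorted(concepts)}"
            )
        return {code.strip().upper() for _system, code in concepts[concept]}

    def cohort_codes(self, condition: str) -> set[str]:
        self._condition(condition)
        return {code.strip().upper() for _s, code in self.cohort_entry[condition]}

    def find_category(self, condition: str, concept: str) -> Category:
        """Locate the category a concept belongs to (error if ambiguous)."""
        hits = [
            cat
            for cat, concepts in self._condition(condition).items()
            if concept in concepts
        ]
        if not hits:
            raise KeyError(f"concept {concept!r} not found under {condition!r}")
        if len(hits) > 1:
            raise KeyError(
                f"concept {concept!r} appears in several categories "
                f"{[c.value for c in hits]}; pass the category explicitly"
            )
        return hits[0]

    def _condition(self, condition: str) -> dict[Category, dict[str, list[tuple[str, str]]]]:
        if condition not in self.entries:
            raise KeyError(
                f"unknown condition {condition!r}; available: {sorted(self.entries)}"
            )
        return self.entries[condition]
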