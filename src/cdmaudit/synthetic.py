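"""Synthetic CDM generator with ground-truth issue injection.

The generator emulates the statistical structure the audits assume:

* a patient population in which each condition cohort is drawn by prevalence;
* per-concept yearly event rates (expected events per active cohort patient
  per year) for diagnoses, procedures, medications and labs;
* a provenance profile drawn once per patient/concept/year — independent
  ordered/billing/claim/derived draws, so a patient can (and often does)
  carry the same diagnosis in several provenance streams;
* medication administrations generated from orders with a configurable
  yearly administration/order ratio schedule (ratios above 1 draw extra
  administrations per order);
* a toy terminology generated jointly with the data, so every clean mapping
  resolves: each drug ingredient family carries an ingredient-level, a
  clinical-drug and a branded code, plus two-ingredient combination codes,
  and each lab code carries a component/specimen/method.

Clean output maps every raw name to exactly one code and vice versa, so the
harmonization audit reports median = min = max = 1 cardinalities and no
critical/major findings.  :func:`inject_issues` then mutates a dataset with
classic harmonization and completeness error classes (wrong code, null code,
brand swap, granularity errors, uninformative renames, shared point-of-care
codes, dropped or decayed record streams) and records every affected record
in a ground-truth ledger, against which :func:`ledger_recall` scores the
audits.
"""

from __future__ import annotations

import datetime as _dt
import enum
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .completeness import DEFAULT_YEARS
from .harmonization import (
    DiscrepancyFinding,
    IssueType,
    RecordDomain,
    select_top_names,
)
from .model import (
    Category,
    CdmDataset,
    CodedEventRecord,
    ConceptLibrary,
    EncounterType,
    EventDomain,
    LabRecord,
    MedAdminRecord,
    MedOrderRecord,
    MethodFlag,
    Provenance,
    TermGranularity,
    TerminologyConcept,
    TerminologyReference,
    TermSystem,
)
from .names import normalize_name

__all__ = [
    "ProvenanceProbs",
    "ConceptSpec",
    "ConditionSpec",
    "GeneratorConfig",
    "IssueClass",
    "IssueSpec",
    "LedgerEntry",
    "GroundTruthLedger",
    "RecallResult",
    "default_conditions",
    "generate_clean",
    "inject_issues",
    "default_issue_specs",
    "ledger_recall",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProvenanceProbs:
    """Independent per-patient-year provenance probabilities for dx/px events."""

    p_ordered: float = 0.65
    p_billed: float = 0.95
    p_claim: float = 0.0
    p_derived: float = 0.0

    def items(self) -> list[tuple[Provenance, float]]:
        return [
            (Provenance.ORDERED, self.p_ordered),
            (Provenance.BILLING, self.p_billed),
            (Provenance.CLAIM, self.p_claim),
            (Provenance.DERIVED, self.p_derived),
        ]


DEFAULT_ENCOUNTER_PROBS: tuple[tuple[EncounterType, float], ...] = (
    (EncounterType.OUTPATIENT, 0.55),
    (EncounterType.INPATIENT, 0.25),
    (EncounterType.EMERGENCY, 0.15),
    (EncounterType.OTHER, 0.05),
)


@dataclass
class ConceptSpec:
    """One clinical concept: category, yearly event rate, optional ratio schedule."""

    label: str
    category: Category
    rate: float = 0.6
    n_codes: int = 2  # dx/px codes per concept
    ratio_schedule: Mapping[int, float] | float = 1.0  # medications only
    codes: list[str] = field(default_factory=list)  # resolved at generation

    def ratio_for(self, year: int) -> float:
        if isinstance(self.ratio_schedule, Mapping):
            return float(self.ratio_schedule.get(year, 1.0))
        return float(self.ratio_schedule)


@dataclass
class ConditionSpec:
    label: str
    prevalence: float
    concepts: list[ConceptSpec]
    p_active: float = 0.9  # probability a cohort member has qualifying care in a year
    provenance: ProvenanceProbs = field(default_factory=ProvenanceProbs)
    encounter_probs: tuple[tuple[EncounterType, float], ...] = DEFAULT_ENCOUNTER_PROBS
    cohort_entry_codes: list[str] = field(default_factory=list)


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_patients: int = 10_000
    years: tuple[int, ...] = DEFAULT_YEARS
    conditions: list[ConditionSpec] | None = None  # None -> default_conditions()
    n_lab_codes: int = 300
    n_drug_families: int = 120
    n_combo_codes: int = 40
    n_poc_lab_codes: int = 10
    background_lab_rate: float = 1.0
    background_order_rate: float = 0.5
    partner_label: str = "synthetic-dp"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        ys = list(self.years)
        if ys != sorted(ys) or any(b - a != 1 for a, b in zip(ys, ys[1:])):
            raise ValueError("years must be contiguous ascending")
        if self.background_lab_rate < 0 or self.background_order_rate < 0:
            raise ValueError("background rates must be >= 0")
        for cond in self.conditions or []:
            if not (0.0 <= cond.prevalence <= 1.0):
                raise ValueError(f"{cond.label}: prevalence must lie in [0, 1]")
            if not (0.0 <= cond.p_active <= 1.0):
                raise ValueError(f"{cond.label}: p_active must lie in [0, 1]")
            for _prov, p in cond.provenance.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{cond.label}: provenance probabilities in [0, 1]")
            total_enc = sum(p for _e, p in cond.encounter_probs)
            if abs(total_enc - 1.0) > 1e-9:
                raise ValueError(f"{cond.label}: encounter probabilities must sum to 1")
            for c in cond.concepts:
                if c.rate < 0:
                    raise ValueError(f"{cond.label}/{c.label}: rate must be >= 0")
                if isinstance(c.ratio_schedule, Mapping):
                    if any(v < 0 for v in c.ratio_schedule.values()):
                        raise ValueError(f"{cond.label}/{c.label}: ratios must be >= 0")
                elif c.ratio_schedule < 0:
                    raise ValueError(f"{cond.label}/{c.label}: ratios must be >= 0")


def default_conditions() -> list[ConditionSpec]:
    """Four study conditions with concept slates spanning all four categories."""

    def cs(label: str, category: Category, rate: float, **kw) -> ConceptSpec:
        return ConceptSpec(label=label, category=category, rate=rate, **kw)

    D, M, P, L = Category.DIAGNOSES, Category.MEDICATIONS, Category.PROCEDURES, Category.LABS
    return [
        ConditionSpec(
            label="chronic_hepatitis_c",
            prevalence=0.03,
            concepts=[
                cs("hepatic_decompensation", D, 0.5),
                cs("hepatitis_b", D, 0.4),
                cs("hiv", D, 0.3),
                cs("interferon", M, 0.5),
                cs("nucleoside_analogue", M, 0.7),
                cs("ns5a_inhibitor", M, 0.6),
                cs("liver_ultrasound", P, 0.6),
                cs("liver_biopsy", P, 0.2),
                cs("albumin_serum", L, 1.2),
                cs("bilirubin", L, 1.2),
                cs("hcv_rna", L, 0.8),
            ],
        ),
        ConditionSpec(
            label="chronic_kidney_disease",
            prevalence=0.12,
            concepts=[
                cs("anemia", D, 0.8),
                cs("hyperkalemia", D, 0.5),
                cs("metabolic_acidosis", D, 0.4),
                cs("pericarditis", D, 0.1),
                cs("uremic_bleeding", D, 0.15),
                cs("dyslipidemia", D, 0.9),
                cs("erythropoiesis_stimulating_agent", M, 0.4),
                cs("iron", M, 0.6),
                cs("ace_inhibitor", M, 1.0),
                cs("beta_blocker", M, 0.9),
                cs("loop_diuretic", M, 0.8),
                cs("dialysis", P, 1.5),
                cs("kidney_biopsy", P, 0.05),
                cs("pyelography", P, 0.08),
                cs("creatinine_serum", L, 2.0),
                cs("blood_urea_nitrogen", L, 1.8),
                cs("hemoglobin", L, 1.5),
                cs("ferritin", L, 0.6),
            ],
        ),
        ConditionSpec(
            label="copd",
            prevalence=0.10,
            concepts=[
                cs("asthma", D, 0.5),
                cs("congestive_heart_failure", D, 0.4),
                cs("diabetes", D, 0.6),
                cs("beta_agonist", M, 1.2),
                cs("muscarinic_antagonist", M, 0.8),
                cs("glucocorticoid", M, 0.9),
                cs("macrolide", M, 0.4),
                cs("fluoroquinolone", M, 0.3),
                cs("chest_xray", P, 1.0),
                cs("pulmonary_function_test", P, 0.5),
                cs("leukocytes", L, 1.2),
                cs("platelets", L, 1.2),
                cs("bicarbonate", L, 0.8),
            ],
        ),
        ConditionSpec(
            label="pulmonary_arterial_hypertension",
            prevalence=0.02,
            concepts=[
                cs("congenital_heart_disease", D, 0.2),
                cs("rheumatoid_arthritis", D, 0.3),
                cs("lupus", D, 0.2),
                cs("prostacyclin", M, 0.5),
                cs("endothelin_antagonist", M, 0.5),
                cs("pde5_inhibitor", M, 0.7),
                cs("echocardiogram", P, 1.0),
                cs("electrocardiogram", P, 1.2),
                cs("bnp", L, 1.0),
                cs("potassium", L, 1.5),
            ],
        ),
    ]


# ---------------------------------------------------------------------------
# Toy terminology
# ---------------------------------------------------------------------------

_SYLLABLES = (
    "ba de fi lo mu ra sa ti vo zu ke pa ne ga xi da ro li ma tu "
    "ce no vi ha su be mi ta fe ku"
).split()

_FORBIDDEN_WORDS = {"poct", "poc", "meter", "wb", "istat", "abs", "pct", "template"}


def _unique_words(rng: np.random.Generator, n: int, used: set[str], suffix: str = "") -> list[str]:
    words: list[str] = []
    while len(words) < n:
        idx = rng.integers(0, len(_SYLLABLES), size=3)
        w = "".join(_SYLLABLES[i] for i in idx) + suffix
        if w in used or w in _FORBIDDEN_WORDS:
            continue
        used.add(w)
        words.append(w)
    return words


@dataclass
class DrugFamily:
    ingredient: str
    brand: str
    strength: int
    form: str
    ingredient_code: str
    clinical_code: str
    branded_code: str

    def raw_name(self, granularity: TermGranularity) -> str:
        if granularity is TermGranularity.INGREDIENT:
            return self.ingredient.upper()
        if granularity is TermGranularity.CLINICAL_DRUG:
            return f"{self.ingredient} {self.strength} MG {self.form}".upper()
        return f"{self.ingredient} {self.strength} MG {self.form} ({self.brand})".upper()


@dataclass
class _Terminology:
    reference: TerminologyReference
    families: list[DrugFamily]
    combo_codes: list[str]
    lab_codes: list[str]  # clinical-lab codes (no POC)
    poc_codes: list[str]
    raw_name_by_code: dict[str, str]
    lab_params: dict[str, tuple[float, float, str]]  # code -> (mu, sd, unit)


_STRENGTHS = (5, 10, 20, 25, 40, 50, 100, 250, 500)
_FORMS = ("tablet", "capsule", "solution", "injection")
_SPECIMENS = ("blood", "serum", "urine", "plasma")
_UNITS = ("mg/dL", "g/dL", "mmol/L", "U/L", "ng/mL")


def _loinc_like(i: int) -> str:
    base = str(10000 + i)
    check = sum(int(d) for d in base) % 10
    return f"{base}-{check}"


def _build_terminology(rng: np.random.Generator, cfg: GeneratorConfig) -> _Terminology:
    used: set[str] = set()
    ingredients = _unique_words(rng, cfg.n_drug_families, used, suffix="in")
    brands = [w.capitalize() for w in _unique_words(rng, cfg.n_drug_families, used, suffix="ex")]
    components = _unique_words(rng, cfg.n_lab_codes, used)

    concepts: list[TerminologyConcept] = []
    raw_name_by_code: dict[str, str] = {}
    families: list[DrugFamily] = []
    for i, (ing, brand) in enumerate(zip(ingredients, brands)):
        strength = _STRENGTHS[i % len(_STRENGTHS)]
        form = _FORMS[i % len(_FORMS)]
        fam = DrugFamily(
            ingredient=ing,
            brand=brand,
            strength=strength,
            form=form,
            ingredient_code=str(100000 + 3 * i),
            clinical_code=str(100001 + 3 * i),
            branded_code=str(100002 + 3 * i),
        )
        families.append(fam)
        concepts.extend(
            [
                TerminologyConcept(
                    code=fam.ingredient_code,
                    system=TermSystem.DRUG,
                    description=ing,
                    ingredients=(ing,),
                    term_granularity=TermGranularity.INGREDIENT,
                ),
                TerminologyConcept(
                    code=fam.clinical_code,
                    system=TermSystem.DRUG,
                    description=f"{ing} {strength} mg oral {form}",
                    ingredients=(ing,),
                    term_granularity=TermGranularity.CLINICAL_DRUG,
                ),
                TerminologyConcept(
                    code=fam.branded_code,
                    system=TermSystem.DRUG,
                    description=f"{ing} {strength} mg oral {form} ({brand})",
                    ingredients=(ing,),
                    term_granularity=TermGranularity.BRANDED_DRUG,
                    brand=brand,
                ),
            ]
        )
        raw_name_by_code[fam.ingredient_code] = fam.raw_name(TermGranularity.INGREDIENT)
        raw_name_by_code[fam.clinical_code] = fam.raw_name(TermGranularity.CLINICAL_DRUG)
        raw_name_by_code[fam.branded_code] = fam.raw_name(TermGranularity.BRANDED_DRUG)

    combo_codes: list[str] = []
    n_combo = min(cfg.n_combo_codes, max(0, len(families) - 1))
    for j in range(n_combo):
        a, b = families[j], families[(j + 1) % len(families)]
        code = str(200000 + j)
        combo_codes.append(code)
        concepts.append(
            TerminologyConcept(
                code=code,
                system=TermSystem.DRUG,
                description=(
                    f"{a.ingredient} {a.strength} mg / {b.ingredient} {b.strength} mg "
                    f"oral {a.form}"
                ),
                ingredients=(a.ingredient, b.ingredient),
                term_granularity=TermGranularity.CLINICAL_DRUG,
            )
        )
        raw_name_by_code[code] = (
            f"{a.ingredient}-{b.ingredient} {a.strength}-{b.strength} MG {a.form}".upper()
        )

    lab_codes: list[str] = []
    poc_codes: list[str] = []
    lab_params: dict[str, tuple[float, float, str]] = {}
    name_templates = ("{c} LVL", "{c}", "{c} BLD", "{c}, SER")
    for i, comp in enumerate(components):
        code = _loinc_like(i)
        is_poc = i >= cfg.n_lab_codes - cfg.n_poc_lab_codes
        specimen = _SPECIMENS[i % len(_SPECIMENS)]
        concepts.append(
            TerminologyConcept(
                code=code,
                system=TermSystem.LAB,
                description=f"{comp.capitalize()} (mass/volume) in {specimen}",
                component=comp,
                specimen=specimen,
                method_flag=MethodFlag.POINT_OF_CARE if is_poc else MethodFlag.CLINICAL_LAB,
            )
        )
        if is_poc:
            poc_codes.append(code)
            raw_name_by_code[code] = f"{comp.upper()} POCT"
        else:
            lab_codes.append(code)
            raw_name_by_code[code] = name_templates[i % len(name_templates)].format(
                c=comp.upper()
            )
        mu = float(rng.uniform(5.0, 300.0))
        lab_params[code] = (mu, 0.15 * mu, _UNITS[i % len(_UNITS)])

    return _Terminology(
        reference=TerminologyReference(concepts),
        families=families,
        combo_codes=combo_codes,
        lab_codes=lab_codes,
        poc_codes=poc_codes,
        raw_name_by_code=raw_name_by_code,
        lab_params=lab_params,
    )


# ---------------------------------------------------------------------------
# Concept-library resolution
# ---------------------------------------------------------------------------

def _resolve_library(
    conditions: list[ConditionSpec], term: _Terminology
) -> tuple[ConceptLibrary, list[ConditionSpec]]:
    """Assign generated codes to every concept and build the library."""
    entries: dict[str, dict[Category, dict[str, list[tuple[str, str]]]]] = {}
    cohort_entry: dict[str, list[tuple[str, str]]] = {}
    fam_cursor = 0
    lab_cursor = 0
    resolved_conditions: list[ConditionSpec] = []
    for ci, cond in enumerate(conditions):
        cond = replace(cond, concepts=[replace(c) for c in cond.concepts])
        cond.cohort_entry_codes = [f"C{ci:02d}.{k}" for k in range(3)]
        cohort_entry[cond.label] = [("SYN-DX", c) for c in cond.cohort_entry_codes]
        cat_map: dict[Category, dict[str, list[tuple[str, str]]]] = {}
        for si, concept in enumerate(cond.concepts):
            if concept.category is Category.MEDICATIONS:
                fam = term.families[fam_cursor % len(term.families)]
                fam_cursor += 1
                concept.codes = [fam.ingredient_code, fam.clinical_code, fam.branded_code]
                pairs = [("SYN-RX", c) for c in concept.codes]
            elif concept.category is Category.LABS:
                codes = [
                    term.lab_codes[(lab_cursor + k) % len(term.lab_codes)] for k in range(2)
                ]
                lab_cursor += 2
                concept.codes = codes
                pairs = [("SYN-LOINC", c) for c in codes]
            else:
                prefix = "D" if concept.category is Category.DIAGNOSES else "P"
                concept.codes = [
                    f"{prefix}{ci:02d}{si:02d}.{k}" for k in range(concept.n_codes)
                ]
                pairs = [("SYN-DX" if prefix == "D" else "SYN-PX", c) for c in concept.codes]
            cat_map.setdefault(concept.category, {})[concept.label] = pairs
        entries[cond.label] = cat_map
        resolved_conditions.append(cond)
    return ConceptLibrary(entries=entries, cohort_entry=cohort_entry), resolved_conditions


# ---------------------------------------------------------------------------
# Clean generation
# ---------------------------------------------------------------------------

class _Accumulator:
    """Column-oriented record accumulator, materialized once at the end."""

    def __init__(self) -> None:
        self.cols: dict[str, list[np.ndarray]] = defaultdict(list)

    def add(self, **arrays: np.ndarray) -> None:
        sizes = {len(a) for a in arrays.values()}
        if len(sizes) > 1:
            raise ValueError("ragged accumulator block")
        if sizes and sizes != {0}:
            for k, a in arrays.items():
                self.cols[k].append(np.asarray(a))

    def get(self, key: str) -> np.ndarray:
        blocks = self.cols.get(key, [])
        if not blocks:
            return np.array([], dtype=object)
        return np.concatenate(blocks)


def _dates(years: np.ndarray, days: np.ndarray) -> list[_dt.date]:
    out = []
    for y, d in zip(years.tolist(), days.tolist()):
        out.append(_dt.date(int(y), 1, 1) + _dt.timedelta(days=int(d)))
    return out


def generate_clean(
    config: GeneratorConfig,
) -> tuple[CdmDataset, TerminologyReference, ConceptLibrary]:
    """Generate a clean (issue-free) dataset, terminology and concept library.

    Deterministic given ``config.seed``: two calls with equal configs return
    identical datasets.
    """
    conditions = config.conditions if config.conditions is not None else default_conditions()
    cfg = replace(config, conditions=conditions)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    term = _build_terminology(rng, cfg)
    library, conditions = _resolve_library(conditions, term)

    n = cfg.n_patients
    pids = np.array([f"P{i:06d}" for i in range(n)])
    enc_unknown = EncounterType.UNKNOWN.value

    ev = _Accumulator()  # diagnosis/procedure events
    od = _Accumulator()  # orders
    ad = _Accumulator()  # administrations
    lb = _Accumulator()  # labs

    def emit_events(
        pidx: np.ndarray,
        counts: np.ndarray,
        year: int,
        codes: Sequence[str],
        domain: str,
        code_system: str,
        cond: ConditionSpec,
    ) -> None:
        """Materialize dx/px events with a per-patient provenance profile."""
        if pidx.size == 0:
            return
        prov_draws = {
            prov: rng.random(pidx.size) < p for prov, p in cond.provenance.items() if p > 0
        }
        enc_values = np.array([e.value for e, _p in cond.encounter_probs])
        enc_probs = np.array([p for _e, p in cond.encounter_probs])
        codes_arr = np.array(list(codes))
        for prov, mask in prov_draws.items():
            sel = mask & (counts > 0)
            if not sel.any():
                continue
            rep_pid = np.repeat(pidx[sel], counts[sel])
            size = rep_pid.size
            ev.add(
                pid=pids[rep_pid],
                year=np.full(size, year),
                day=rng.integers(0, 365, size),
                code=codes_arr[rng.integers(0, len(codes_arr), size)],
                domain=np.full(size, domain, dtype=object),
                system=np.full(size, code_system, dtype=object),
                provenance=np.full(size, prov.value, dtype=object),
                encounter=enc_values[
                    rng.choice(len(enc_values), size=size, p=enc_probs)
                ],
            )

    # condition cohorts
    for cond in conditions:
        members = np.where(rng.random(n) < cond.prevalence)[0]
        for year in cfg.years:
            active = members[rng.random(members.size) < cond.p_active]
            if active.size == 0:
                continue
            # cohort-entry diagnoses define cohort membership for the year
            entry_counts = 1 + rng.poisson(0.3, active.size)
            emit_events(
                active, entry_counts, year, cond.cohort_entry_codes,
                EventDomain.DIAGNOSIS.value, "SYN-DX", cond,
            )
            for concept in cond.concepts:
                k = rng.poisson(concept.rate, active.size)
                if concept.category is Category.DIAGNOSES:
                    emit_events(
                        active, k, year, concept.codes,
                        EventDomain.DIAGNOSIS.value, "SYN-DX", cond,
                    )
                elif concept.category is Category.PROCEDURES:
                    emit_events(
                        active, k, year, concept.codes,
                        EventDomain.PROCEDURE.value, "SYN-PX", cond,
                    )
                elif concept.category is Category.MEDICATIONS:
                    order_pid = np.repeat(active, k)
                    n_orders = order_pid.size
                    if n_orders == 0:
                        continue
                    code = concept.codes[1]  # clinical-drug code carries the volume
                    od.add(
                        pid=pids[order_pid],
                        year=np.full(n_orders, year),
                        day=rng.integers(0, 365, n_orders),
                        code=np.full(n_orders, code, dtype=object),
                    )
                    ratio = concept.ratio_for(year)
                    base = (rng.random(n_orders) < min(ratio, 1.0)).astype(np.int64)
                    extra = (
                        rng.poisson(ratio - 1.0, n_orders)
                        if ratio > 1.0
                        else np.zeros(n_orders, dtype=np.int64)
                    )
                    n_adm = base + extra
                    adm_pid = np.repeat(order_pid, n_adm)
                    if adm_pid.size:
                        ad.add(
                            pid=pids[adm_pid],
                            year=np.full(adm_pid.size, year),
                            day=rng.integers(0, 365, adm_pid.size),
                            code=np.full(adm_pid.size, code, dtype=object),
                        )
                else:  # labs
                    lab_pid = np.repeat(active, k)
                    if lab_pid.size == 0:
                        continue
                    codes_arr = np.array(concept.codes, dtype=object)
                    code_idx = rng.integers(0, len(codes_arr), lab_pid.size)
                    code = codes_arr[code_idx]
                    mus = np.array([term.lab_params[c][0] for c in concept.codes])
                    sds = np.array([term.lab_params[c][1] for c in concept.codes])
                    lb.add(
                        pid=pids[lab_pid],
                        year=np.full(lab_pid.size, year),
                        day=rng.integers(0, 365, lab_pid.size),
                        code=code,
                        value=rng.normal(mus[code_idx], sds[code_idx]),
                    )

    # background volume across the whole population
    bg_lab_codes = np.array(term.lab_codes + term.poc_codes, dtype=object)
    bg_lab_mu = np.array([term.lab_params[c][0] for c in bg_lab_codes])
    bg_lab_sd = np.array([term.lab_params[c][1] for c in bg_lab_codes])
    bg_order_codes = np.array(
        [f.clinical_code for f in term.families] + term.combo_codes, dtype=object
    )
    for year in cfg.years:
        k = rng.poisson(cfg.background_lab_rate, n)
        rep = np.repeat(np.arange(n), k)
        if rep.size:
            idx = rng.integers(0, len(bg_lab_codes), rep.size)
            lb.add(
                pid=pids[rep],
                year=np.full(rep.size, year),
                day=rng.integers(0, 365, rep.size),
                code=bg_lab_codes[idx],
                value=rng.normal(bg_lab_mu[idx], bg_lab_sd[idx]),
            )
        k = rng.poisson(cfg.background_order_rate, n)
        rep = np.repeat(np.arange(n), k)
        if rep.size:
            code = bg_order_codes[rng.integers(0, len(bg_order_codes), rep.size)]
            od.add(
                pid=pids[rep],
                year=np.full(rep.size, year),
                day=rng.integers(0, 365, rep.size),
                code=code,
            )
            # one administration per background order (stable 100% ratio)
            ad.add(
                pid=pids[rep],
                year=np.full(rep.size, year),
                day=rng.integers(0, 365, rep.size),
                code=code.copy(),
            )

    # materialize
    name_of = term.raw_name_by_code
    dataset = CdmDataset(partner_label=cfg.partner_label)

    dates = _dates(ev.get("year"), ev.get("day"))
    dataset.events = [
        CodedEventRecord(
            patient_id=str(p),
            record_id=f"E{i:08d}",
            event_date=d,
            domain=EventDomain(dom),
            code=str(c),
            code_system=s,
            provenance=Provenance(pv),
            encounter_type=EncounterType(e),
        )
        for i, (p, d, dom, c, s, pv, e) in enumerate(
            zip(
                ev.get("pid"), dates, ev.get("domain"), ev.get("code"),
                ev.get("system"), ev.get("provenance"), ev.get("encounter"),
            )
        )
    ]
    dates = _dates(od.get("year"), od.get("day"))
    dataset.orders = [
        MedOrderRecord(
            patient_id=str(p), record_id=f"O{i:08d}", order_date=d,
            raw_name=name_of[c], code=str(c),
        )
        for i, (p, d, c) in enumerate(zip(od.get("pid"), dates, od.get("code")))
    ]
    dates = _dates(ad.get("year"), ad.get("day"))
    dataset.administrations = [
        MedAdminRecord(
            patient_id=str(p), record_id=f"A{i:08d}", admin_date=d,
            raw_name=name_of[c], code=str(c),
        )
        for i, (p, d, c) in enumerate(zip(ad.get("pid"), dates, ad.get("code")))
    ]
    dates = _dates(lb.get("year"), lb.get("day"))
    dataset.labs = [
        LabRecord(
            patient_id=str(p), record_id=f"L{i:08d}", result_date=d,
            raw_name=name_of[c], code=str(c),
            numeric_result=round(float(v), 3),
            result_unit=term.lab_params[c][2],
        )
        for i, (p, d, c, v) in enumerate(
            zip(lb.get("pid"), dates, lb.get("code"), lb.get("value"))
        )
    ]
    return dataset, term.reference, library


# ---------------------------------------------------------------------------
# Issue injection
# ---------------------------------------------------------------------------

class IssueClass(str, enum.Enum):
    WRONG_CODE = "wrong_code"
    NULL_CODE = "null_code"
    GENERIC_NAME_BRAND_CODE = "generic_name_brand_code"
    INGREDIENT_LEVEL_CODE = "ingredient_level_code"
    SINGLE_INGREDIENT_TO_MULTI_CODE = "single_ingredient_to_multi_code"
    MULTI_INGREDIENT_TO_SINGLE_CODE = "multi_ingredient_to_single_code"
    MIXTURE_MULTI_CODE = "mixture_multi_code"
    UNINFORMATIVE_RENAME = "uninformative_rename"
    POC_CLINICAL_SHARED_CODE = "poc_clinical_shared_code"
    DROP_ORDER_STREAM = "drop_order_stream"
    DROP_PROVENANCE_STREAM = "drop_provenance_stream"
    DECAY_ADMIN_RATIO = "decay_admin_ratio"


#: Finding types that count as detection of each harmonization issue class.
EXPECTED_FINDINGS: dict[IssueClass, frozenset[IssueType]] = {
    IssueClass.WRONG_CODE: frozenset(
        {IssueType.INGREDIENT_MISMATCH, IssueType.LAB_TEST_MISMATCH}
    ),
    IssueClass.NULL_CODE: frozenset({IssueType.NULL_CODE}),
    IssueClass.GENERIC_NAME_BRAND_CODE: frozenset({IssueType.GENERIC_NAME_BRAND_CODE}),
    IssueClass.INGREDIENT_LEVEL_CODE: frozenset({IssueType.INGREDIENT_LEVEL_CODE}),
    IssueClass.SINGLE_INGREDIENT_TO_MULTI_CODE: frozenset(
        {IssueType.SINGLE_INGREDIENT_TO_MULTI_CODE}
    ),
    IssueClass.MULTI_INGREDIENT_TO_SINGLE_CODE: frozenset(
        {IssueType.MULTI_INGREDIENT_TO_SINGLE_CODE}
    ),
    IssueClass.MIXTURE_MULTI_CODE: frozenset({IssueType.MIXTURE_MULTI_CODE}),
    IssueClass.UNINFORMATIVE_RENAME: frozenset({IssueType.UNINFORMATIVE_NAME}),
    IssueClass.POC_CLINICAL_SHARED_CODE: frozenset({IssueType.POC_CLINICAL_SHARED_CODE}),
}


@dataclass
class IssueSpec:
    """One injected issue: class, target, class-specific magnitude.

    Harmonization classes target a raw name (``target`` = name string,
    ``domain`` = orders/administrations/labs).  Completeness classes target
    a concept (``target`` = "condition/concept").  ``magnitude``:

    * wrong_code / null_code / code swaps: fraction of the name's records to
      mutate (default 1.0);
    * uninformative_rename: "template" or "integer" naming style;
    * poc_clinical_shared_code: fraction of records renamed to the
      point-of-care variant (default 0.5);
    * decay_admin_ratio: mapping year -> keep fraction for administrations;
    * drop_provenance_stream: provenance value to delete.
    """

    issue_class: IssueClass
    target: str
    domain: RecordDomain | None = None
    magnitude: object = None


@dataclass
class LedgerEntry:
    issue_class: IssueClass
    target: str
    detect_key: str  # raw name (post-mutation) or "condition/concept"
    domain: RecordDomain | None
    affected_record_ids: list[str]
    expected_detection: bool = True
    note: str = ""


@dataclass
class GroundTruthLedger:
    entries: list[LedgerEntry] = field(default_factory=list)

    def by_class(self) -> dict[IssueClass, list[LedgerEntry]]:
        out: dict[IssueClass, list[LedgerEntry]] = defaultdict(list)
        for e in self.entries:
            out[e.issue_class].append(e)
        return dict(out)

    def detect_keys(self) -> set[str]:
        return {normalize_name(e.detect_key).key for e in self.entries}


_DOMAIN_ATTR = {
    RecordDomain.ORDERS: "orders",
    RecordDomain.ADMINISTRATIONS: "administrations",
    RecordDomain.LABS: "labs",
}


def _records_for_name(records: list, name: str) -> list:
    key = normalize_name(name).key
    return [r for r in records if normalize_name(r.raw_name).key == key]


def _concept_lookup(library: ConceptLibrary, target: str) -> tuple[str, str, Category, set[str]]:
    if "/" not in target:
        raise ValueError(
            f"completeness issue target must be 'condition/concept', got {target!r}"
        )
    condition, concept = target.split("/", 1)
    category = library.find_category(condition, concept)
    return condition, concept, category, library.codes(condition, category, concept)


def inject_issues(
    dataset: CdmDataset,
    terminology: TerminologyReference,
    specs: Sequence[IssueSpec],
    seed: int = 0,
    library: ConceptLibrary | None = None,
) -> tuple[CdmDataset, GroundTruthLedger]:
    """Apply issue specs to a dataset (mutated in place) with a ground-truth ledger.

    Deterministic given ``seed``.  Completeness classes (drop/decay streams)
    need ``library`` to resolve concept code lists.
    """
    rng = np.random.default_rng(seed)
    ledger = GroundTruthLedger()
    for spec in specs:
        cls = IssueClass(spec.issue_class)
        if cls in (
            IssueClass.DROP_ORDER_STREAM,
            IssueClass.DROP_PROVENANCE_STREAM,
            IssueClass.DECAY_ADMIN_RATIO,
        ):
            if library is None:
                raise ValueError(f"{cls.value} injection requires a concept library")
            ledger.entries.append(_inject_stream_issue(dataset, library, spec, rng))
        else:
            ledger.entries.append(_inject_name_issue(dataset, terminology, spec, rng))
    return dataset, ledger


def _inject_name_issue(
    dataset: CdmDataset,
    ref: TerminologyReference,
    spec: IssueSpec,
    rng: np.random.Generator,
) -> LedgerEntry:
    cls = IssueClass(spec.issue_class)
    domain = spec.domain or RecordDomain.ORDERS
    records = getattr(dataset, _DOMAIN_ATTR[domain])
    targets = _records_for_name(records, spec.target)
    if not targets:
        raise ValueError(f"target name {spec.target!r} not found in {domain.value}")
    nn = normalize_name(spec.target)
    detect_key = spec.target
    affected: list[str] = []

    def subset(fraction: float) -> list:
        if fraction >= 1.0:
            return targets
        k = max(1, int(round(fraction * len(targets))))
        idx = rng.choice(len(targets), size=k, replace=False)
        return [targets[i] for i in sorted(idx.tolist())]

    if cls is IssueClass.NULL_CODE:
        for r in subset(float(spec.magnitude or 1.0)):
            r.code = None
            affected.append(r.record_id)
    elif cls is IssueClass.WRONG_CODE:
        current = ref.get(targets[0].code)
        replacement = _pick_disjoint_code(ref, nn, current)
        for r in subset(float(spec.magnitude or 1.0)):
            r.code = replacement
            affected.append(r.record_id)
    elif cls in (
        IssueClass.GENERIC_NAME_BRAND_CODE,
        IssueClass.INGREDIENT_LEVEL_CODE,
        IssueClass.SINGLE_INGREDIENT_TO_MULTI_CODE,
        IssueClass.MULTI_INGREDIENT_TO_SINGLE_CODE,
    ):
        replacement = _pick_swap_code(ref, cls, targets[0].code)
        for r in targets:
            r.code = replacement
            affected.append(r.record_id)
    elif cls is IssueClass.MIXTURE_MULTI_CODE:
        current = ref.get(targets[0].code)
        if current is None or len(current.ingredients) < 2:
            raise ValueError(
                f"mixture injection needs a multi-ingredient-coded target, got "
                f"{spec.target!r}"
            )
        split_codes = [
            _single_ingredient_code(ref, ing, TermGranularity.CLINICAL_DRUG)
            for ing in current.ingredients
        ]
        new_records = []
        for r in targets:
            records.remove(r)
            affected.append(r.record_id)
            for j, code in enumerate(split_codes):
                dup = replace(r, record_id=f"{r.record_id}x{j}", code=code)
                new_records.append(dup)
                affected.append(dup.record_id)
        records.extend(new_records)
    elif cls is IssueClass.UNINFORMATIVE_RENAME:
        style = str(spec.magnitude or "template")
        if style == "integer":
            detect_key = str(int(rng.integers(100000, 999999)))
        else:
            detect_key = "ZZ IMS TEMPLATE"
        for r in targets:
            r.raw_name = detect_key
            affected.append(r.record_id)
    elif cls is IssueClass.POC_CLINICAL_SHARED_CODE:
        detect_key = f"{spec.target}, POCT"
        for r in subset(float(spec.magnitude or 0.5)):
            r.raw_name = detect_key
            affected.append(r.record_id)
    else:
        raise ValueError(f"issue class {cls.value} incompatible with a raw-name target")
    return LedgerEntry(
        issue_class=cls,
        target=spec.target,
        detect_key=detect_key,
        domain=domain,
        affected_record_ids=affected,
    )


def _pick_disjoint_code(ref, nn, current) -> str:
    """A code whose concept shares no token with the name (a true mapping error)."""
    is_drug = current is None or current.system is TermSystem.DRUG
    pool = ref.drug_concepts() if is_drug else ref.lab_concepts()
    for c in sorted(pool, key=lambda c: c.code):
        if is_drug and len(c.ingredients) != 1:
            continue
        if not (normalize_name(c.description).all_tokens & nn.all_tokens):
            return c.code
    raise ValueError("no token-disjoint replacement code available")


def _single_ingredient_code(ref, ingredient: str, granularity: TermGranularity) -> str:
    want = normalize_name(ingredient).all_tokens
    for c in sorted(ref.drug_concepts(), key=lambda c: c.code):
        if (
            len(c.ingredients) == 1
            and c.term_granularity is granularity
            and normalize_name(c.ingredients[0]).all_tokens == want
        ):
            return c.code
    raise ValueError(f"no {granularity.value} code for ingredient {ingredient!r}")


def _pick_swap_code(ref, cls: IssueClass, current_code: str | None) -> str:
    current = ref.get(current_code)
    if current is None:
        raise ValueError(f"target's code {current_code!r} not in terminology")
    if cls is IssueClass.GENERIC_NAME_BRAND_CODE:
        for c in sorted(ref.drug_concepts(), key=lambda c: c.code):
            if (
                c.term_granularity is TermGranularity.BRANDED_DRUG
                and c.ingredients == current.ingredients
            ):
                return c.code
        raise ValueError("no branded counterpart code available")
    if cls is IssueClass.INGREDIENT_LEVEL_CODE:
        return _single_ingredient_code(
            ref, current.ingredients[0], TermGranularity.INGREDIENT
        )
    if cls is IssueClass.SINGLE_INGREDIENT_TO_MULTI_CODE:
        ing = normalize_name(current.ingredients[0]).all_tokens
        multis = [c for c in ref.drug_concepts() if len(c.ingredients) >= 2]
        for c in sorted(multis, key=lambda c: c.code):
            if any(normalize_name(i).all_tokens == ing for i in c.ingredients):
                return c.code
        if not multis:
            raise ValueError("terminology holds no multi-ingredient codes")
        return sorted(multis, key=lambda c: c.code)[0].code
    # multi -> single: keep the first ingredient only
    if len(current.ingredients) < 2:
        raise ValueError("multi->single swap needs a multi-ingredient-coded target")
    return _single_ingredient_code(
        ref, current.ingredients[0], TermGranularity.CLINICAL_DRUG
    )


def _inject_stream_issue(
    dataset: CdmDataset,
    library: ConceptLibrary,
    spec: IssueSpec,
    rng: np.random.Generator,
) -> LedgerEntry:
    cls = IssueClass(spec.issue_class)
    condition, concept, category, codes = _concept_lookup(library, spec.target)
    affected: list[str] = []
    if cls is IssueClass.DROP_ORDER_STREAM:
        kept = []
        for r in dataset.orders:
            if (r.code or "").strip().upper() in codes:
                affected.append(r.record_id)
            else:
                kept.append(r)
        dataset.orders = kept
        note = "orders deleted; administrations now lack a denominator"
    elif cls is IssueClass.DECAY_ADMIN_RATIO:
        schedule = spec.magnitude
        if not isinstance(schedule, Mapping):
            raise ValueError("decay_admin_ratio magnitude must map year -> keep fraction")
        kept = []
        for r in dataset.administrations:
            keep_p = float(schedule.get(r.admin_date.year, 1.0))
            if (r.code or "").strip().upper() in codes and rng.random() >= keep_p:
                affected.append(r.record_id)
            else:
                kept.append(r)
        dataset.administrations = kept
        note = "administrations thinned by yearly factors"
    else:  # DROP_PROVENANCE_STREAM
        prov = Provenance(str(spec.magnitude or Provenance.ORDERED.value))
        kept_ev = []
        for e in dataset.events:
            if e.code.strip().upper() in codes and e.provenance is prov:
                affected.append(e.record_id)
            else:
                kept_ev.append(e)
        dataset.events = kept_ev
        note = f"all {prov.value} records removed for the concept"
    return LedgerEntry(
        issue_class=cls,
        target=spec.target,
        detect_key=spec.target,
        domain=None,
        affected_record_ids=affected,
        note=note,
    )


# ---------------------------------------------------------------------------
# Default issue slate (one per class, targeting top-volume names)
# ---------------------------------------------------------------------------

def default_issue_specs(
    dataset: CdmDataset,
    ref: TerminologyReference,
    top_n: int = 200,
    library: ConceptLibrary | None = None,
) -> list[IssueSpec]:
    """One harmonization issue per class, each targeting a distinct top-name.

    Deterministic: eligible names are taken in rank order from the top-N
    selection of each domain.  When a concept library is given, names whose
    code belongs to a library concept are skipped, so harmonization
    injections do not also perturb the completeness ratio series.
    """
    excluded_codes: set[str] = set()
    if library is not None:
        for condition in library.conditions():
            for category in library.categories(condition):
                for concept in library.concepts(condition, category):
                    excluded_codes |= library.codes(condition, category, concept)
    order_sel = select_top_names(dataset.orders, n=top_n, domain=RecordDomain.ORDERS)
    admin_sel = select_top_names(
        dataset.administrations, n=top_n, domain=RecordDomain.ADMINISTRATIONS
    )
    lab_sel = select_top_names(dataset.labs, n=top_n, domain=RecordDomain.LABS)

    def first_code(records, name):
        for r in records:
            if normalize_name(r.raw_name).key == normalize_name(name).key:
                return r.code
        return None

    def eligible(sel, records, predicate, k, exclude_library_codes=True):
        out = []
        for name in sel.names:
            c = ref.get(first_code(records, name))
            if c is None:
                continue
            if exclude_library_codes and c.code.strip().upper() in excluded_codes:
                continue
            if predicate(c):
                out.append(name)
            if len(out) == k:
                break
        return out

    single_clin = eligible(
        order_sel,
        dataset.orders,
        lambda c: c.term_granularity is TermGranularity.CLINICAL_DRUG
        and len(c.ingredients) == 1,
        5,
    )
    combos = eligible(order_sel, dataset.orders, lambda c: len(c.ingredients) >= 2, 1)
    admin_combos = eligible(
        admin_sel, dataset.administrations, lambda c: len(c.ingredients) >= 2, 1
    )
    admin_single = eligible(
        admin_sel,
        dataset.administrations,
        lambda c: c.term_granularity is TermGranularity.CLINICAL_DRUG
        and len(c.ingredients) == 1,
        1,
    )
    # Lab renames keep the code, so concept lab names stay fair game: the
    # completeness lab counts match on code and are unaffected.
    clin_labs = eligible(
        lab_sel, dataset.labs, lambda c: c.method_flag is MethodFlag.CLINICAL_LAB, 1,
        exclude_library_codes=False,
    )
    need = {
        "single-ingredient clinical-drug order names": (single_clin, 5),
        "combination-coded order names": (combos, 1),
        "combination-coded administration names": (admin_combos, 1),
        "single-ingredient administration names": (admin_single, 1),
        "clinical-lab names": (clin_labs, 1),
    }
    for what, (got, k) in need.items():
        if len(got) < k:
            raise ValueError(f"dataset too small to choose {what}")

    O, A, L = RecordDomain.ORDERS, RecordDomain.ADMINISTRATIONS, RecordDomain.LABS
    return [
        IssueSpec(IssueClass.WRONG_CODE, single_clin[0], O),
        IssueSpec(IssueClass.NULL_CODE, single_clin[1], O),
        IssueSpec(IssueClass.GENERIC_NAME_BRAND_CODE, single_clin[2], O),
        IssueSpec(IssueClass.INGREDIENT_LEVEL_CODE, single_clin[3], O),
        IssueSpec(IssueClass.SINGLE_INGREDIENT_TO_MULTI_CODE, single_clin[4], O),
        IssueSpec(IssueClass.MULTI_INGREDIENT_TO_SINGLE_CODE, combos[0], O),
        IssueSpec(IssueClass.MIXTURE_MULTI_CODE, admin_combos[0], A),
        IssueSpec(IssueClass.UNINFORMATIVE_RENAME, admin_single[0], A, "template"),
        IssueSpec(IssueClass.POC_CLINICAL_SHARED_CODE, clin_labs[0], L),
    ]


# ---------------------------------------------------------------------------
# Ledger-based recall/precision scoring
# ---------------------------------------------------------------------------

@dataclass
class ClassRecall:
    n_expected: int
    n_detected: int

    @property
    def recall(self) -> float:
        return self.n_detected / self.n_expected if self.n_expected else 1.0


@dataclass
class RecallResult:
    per_class: dict[IssueClass, ClassRecall]
    overall_recall: float
    precision: float
    false_positive_keys: list[str] = field(default_factory=list)


def ledger_recall(
    ledger: GroundTruthLedger,
    findings: Sequence[DiscrepancyFinding] = (),
    ratio_flags: Mapping[tuple[str, str], set[str]] | None = None,
    stratified_counts: Sequence = (),
) -> RecallResult:
    """Score audit output against the injection ledger.

    A harmonization entry is detected when a finding of the class's expected
    issue type(s) references the (post-mutation) target name; stream entries
    are detected through ratio flags (extreme/zero_orders for dropped orders,
    drift for decayed administrations) or an emptied provenance stratum.
    Precision is computed over distinct flagged names/concepts.
    """
    ratio_flags = ratio_flags or {}
    finding_types: dict[str, set[IssueType]] = defaultdict(set)
    for f in findings:
        finding_types[f.entry.name_key].add(f.issue_type)

    per_class: dict[IssueClass, ClassRecall] = {}
    detected_keys: set[str] = set()
    for cls, entries in ledger.by_class().items():
        n_expected = sum(1 for e in entries if e.expected_detection)
        n_detected = 0
        for e in entries:
            if not e.expected_detection:
                continue
            if cls in EXPECTED_FINDINGS:
                key = normalize_name(e.detect_key).key
                if finding_types.get(key, set()) & EXPECTED_FINDINGS[cls]:
                    n_detected += 1
                    detected_keys.add(key)
            else:
                cond_concept = tuple(e.target.split("/", 1))
                flags = ratio_flags.get(cond_concept, set())
                if cls is IssueClass.DROP_ORDER_STREAM:
                    hit = bool(flags & {"extreme", "zero_orders"})
                elif cls is IssueClass.DECAY_ADMIN_RATIO:
                    hit = "drift" in flags
                else:  # DROP_PROVENANCE_STREAM
                    prov_rows = [
                        c
                        for c in stratified_counts
                        if (c.condition, c.concept) == cond_concept
                        and c.stratifier.value == "provenance"
                    ]
                    hit = any(
                        c.n_patients == 0 and c.concept_total > 0 for c in prov_rows
                    )
                if hit:
                    n_detected += 1
                    detected_keys.add(e.target)
        per_class[cls] = ClassRecall(n_expected=n_expected, n_detected=n_detected)

    total_expected = sum(c.n_expected for c in per_class.values())
    total_detected = sum(c.n_detected for c in per_class.values())
    overall = total_detected / total_expected if total_expected else 1.0

    ledger_keys = ledger.detect_keys() | {e.target for e in ledger.entries}
    positives: set[str] = set(finding_types)
    for (cond, concept), flags in ratio_flags.items():
        if flags & {"drift", "extreme", "zero_orders"}:
            positives.add(f"{cond}/{concept}")
    false_pos = sorted(k for k in positives if k not in ledger_keys)
    precision = (
        (len(positives) - len(false_pos)) / len(positives) if positives else 1.0
    )
    return RecallResult(
        per_class=per_class,
        overall_recall=overall,
        precision=precision,
        false_positive_keys=false_pos,
    )
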