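"""Shared fixtures: hand-built toy terminology and session-scoped synthetic
datasets (generation is deterministic, so sharing across tests is safe)."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import settings

from cdmaudit.completeness import completeness_report
from cdmaudit.harmonization import harmonization_report
from cdmaudit.model import (
    LabRecord,
    MedOrderRecord,
    MethodFlag,
    TermGranularity,
    TerminologyConcept,
    TerminologyReference,
    TermSystem,
)
from cdmaudit.synthetic import (
    GeneratorConfig,
    IssueClass,
    IssueSpec,
    default_issue_specs,
    generate_clean,
    inject_issues,
    ledger_recall,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def lab(pid, rid, name, code=None, value=None, date=dt.date(2018, 3, 1)):
    return LabRecord(
        patient_id=pid, record_id=rid, result_date=date, raw_name=name,
        code=code, numeric_result=value,
    )


def order(pid, rid, name, code=None, date=dt.date(2018, 3, 1)):
    return MedOrderRecord(
        patient_id=pid, record_id=rid, order_date=date, raw_name=name, code=code
    )


@pytest.fixture(scope="session")
def toy_terminology() -> TerminologyReference:
    """Hand-built reference with one drug family, a combo, and a few labs."""
    return TerminologyReference(
        [
            TerminologyConcept(
                code="29046", system=TermSystem.DRUG, description="lisinopril",
                ingredients=("lisinopril",), term_granularity=TermGranularity.INGREDIENT,
            ),
            TerminologyConcept(
                code="311354", system=TermSystem.DRUG,
                description="lisinopril 5 mg oral tablet",
                ingredients=("lisinopril",),
                term_granularity=TermGranularity.CLINICAL_DRUG,
            ),
            TerminologyConcept(
                code="206765", system=TermSystem.DRUG,
                description="lisinopril 5 mg oral tablet (Zestril)",
                ingredients=("lisinopril",),
                term_granularity=TermGranularity.BRANDED_DRUG, brand="Zestril",
            ),
            TerminologyConcept(
                code="1049221", system=TermSystem.DRUG,
                description="acetaminophen 325 mg / oxycodone hydrochloride 2.5 mg oral tablet",
                ingredients=("acetaminophen", "oxycodone"),
                term_granularity=TermGranularity.CLINICAL_DRUG,
            ),
            TerminologyConcept(
                code="1658717", system=TermSystem.DRUG,
                description="heparin sodium 1000 unt/mL injectable solution",
                ingredients=("heparin",),
                term_granularity=TermGranularity.CLINICAL_DRUG,
            ),
            TerminologyConcept(
                code="103418", system=TermSystem.DRUG,
                description="lidocaine 20 mg/mL topical cream",
                ingredients=("lidocaine",),
                term_granularity=TermGranularity.CLINICAL_DRUG,
            ),
            TerminologyConcept(
                code="2345-7", system=TermSystem.LAB,
                description="Glucose (mass/volume) in serum or plasma",
                component="glucose", specimen="serum",
                method_flag=MethodFlag.CLINICAL_LAB,
            ),
            TerminologyConcept(
                code="711-2", system=TermSystem.LAB,
                description="Eosinophils (#/volume) in blood by automated count",
                component="eosinophils", specimen="blood",
                method_flag=MethodFlag.CLINICAL_LAB,
            ),
            TerminologyConcept(
                code="2160-0", system=TermSystem.LAB,
                description="Creatinine (mass/volume) in serum or plasma",
                component="creatinine", specimen="serum",
                method_flag=MethodFlag.CLINICAL_LAB,
            ),
            TerminologyConcept(
                code="2075-0", system=TermSystem.LAB,
                description="Chloride (moles/volume) in serum or plasma",
                component="chloride", specimen="serum",
                method_flag=MethodFlag.CLINICAL_LAB,
            ),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Small clean synthetic dataset (~300 patients) for unit-level checks."""
    return generate_clean(GeneratorConfig(seed=5, n_patients=300))


@pytest.fixture(scope="session")
def clean_10k_bundle():
    """The clean-data study condition: 10 000 patients, default generator."""
    return generate_clean(GeneratorConfig(seed=101, n_patients=10_000))


@pytest.fixture(scope="session")
def clean_10k_harmonization(clean_10k_bundle):
    dataset, ref, _library = clean_10k_bundle
    return harmonization_report(dataset, ref, n=200)


STREAM_SPECS = [
    IssueSpec(
        IssueClass.DROP_ORDER_STREAM,
        "chronic_kidney_disease/erythropoiesis_stimulating_agent",
    ),
    IssueSpec(
        IssueClass.DECAY_ADMIN_RATIO,
        "chronic_kidney_disease/iron",
        magnitude={2016: 1.0, 2017: 0.8, 2018: 0.5, 2019: 0.25, 2020: 0.25, 2021: 0.25},
    ),
    IssueSpec(
        IssueClass.DROP_PROVENANCE_STREAM,
        "chronic_kidney_disease/pericarditis",
        magnitude="ordered",
    ),
]


@pytest.fixture(scope="session")
def injected_bundle():
    """2000-patient dataset with one injected issue per error class, audited."""
    dataset, ref, library = generate_clean(GeneratorConfig(seed=202, n_patients=2000))
    specs = default_issue_specs(dataset, ref, library=library) + STREAM_SPECS
    dataset, ledger = inject_issues(dataset, ref, specs, seed=202, library=library)
    harm = harmonization_report(dataset, ref, n=200)
    comp = completeness_report(dataset, library)
    result = ledger_recall(
        ledger,
        findings=harm.findings,
        ratio_flags=comp.flagged_concepts(),
        stratified_counts=comp.counts,
    )
    return {
        "dataset": dataset,
        "ref": ref,
        "library": library,
        "ledger": ledger,
        "harmonization": harm,
        "completeness": comp,
        "recall": result,
    }
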