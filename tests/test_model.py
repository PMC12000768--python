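import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdmaudit.model import (
    CdmDataset,
    Category,
    ConceptLibrary,
    EncounterType,
    EventDomain,
    CodedEventRecord,
    Provenance,
    TermGranularity,
    TerminologyConcept,
    TerminologyReference,
    TermSystem,
    coerce_encounter_type,
    coerce_provenance,
)


class TestEnumCoercion:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("OD", Provenance.ORDERED),
            ("BI", Provenance.BILLING),
            ("CL", Provenance.CLAIM),
            ("DR", Provenance.DERIVED),
            ("billed", Provenance.BILLING),
            ("ordered", Provenance.ORDERED),
            ("??", Provenance.UNKNOWN),
            (None, Provenance.UNKNOWN),
        ],
    )
    def test_provenance_aliases(self, raw, expected):
        assert coerce_provenance(raw) is expected

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("AV", EncounterType.OUTPATIENT),
            ("IP", EncounterType.INPATIENT),
            ("ED", EncounterType.EMERGENCY),
            ("OT", EncounterType.OTHER),
            ("EI", EncounterType.INPATIENT),
            ("", EncounterType.UNKNOWN),
        ],
    )
    def test_encounter_aliases(self, raw, expected):
        assert coerce_encounter_type(raw) is expected

    @given(st.text(max_size=12))
    def test_coercion_is_total(self, raw):
        """Every input string lands on exactly one member of the closed enum,
        so stratified counts over the enum partition the records."""
        assert coerce_provenance(raw) in Provenance
        assert coerce_encounter_type(raw) in EncounterType


class TestTerminologyTypes:
    def test_lab_concept_rejects_ingredients(self):
        with pytest.raises(ValueError):
            TerminologyConcept(
                code="1-1", system=TermSystem.LAB, description="x",
                ingredients=("a",),
            )

    def test_drug_concept_needs_ingredients(self):
        with pytest.raises(ValueError):
            TerminologyConcept(code="1", system=TermSystem.DRUG, description="x")

    def test_drug_concept_rejects_component(self):
        with pytest.raises(ValueError):
            TerminologyConcept(
                code="1", system=TermSystem.DRUG, description="x",
                ingredients=("a",), component="c",
            )

    def test_duplicate_codes_rejected(self):
        c = TerminologyConcept(
            code="7", system=TermSystem.DRUG, description="a", ingredients=("a",),
            term_granularity=TermGranularity.INGREDIENT,
        )
        with pytest.raises(ValueError, match="duplicate"):
            TerminologyReference([c, c])

    def test_vocabularies_are_built(self, toy_terminology):
        assert "lisinopril" in toy_terminology.ingredient_vocabulary
        assert "glucose" in toy_terminology.component_vocabulary
        assert "zestril" in toy_terminology.brand_vocabulary


class TestConceptLibrary:
    def _entries(self):
        return {
            "ckd": {
                Category.DIAGNOSES: {"anemia": [("ICD10", "D64.9"), ("ICD10", "D50.0")]}
            }
        }

    def test_missing_cohort_entry_rejected(self):
        with pytest.raises(ValueError, match="cohort_entry"):
            ConceptLibrary(entries=self._entries(), cohort_entry={"ckd": []})

    def test_codes_are_normalized(self):
        lib = ConceptLibrary(
            entries=self._entries(), cohort_entry={"ckd": [("ICD10", "n18.3 ")]}
        )
        assert lib.cohort_codes("ckd") == {"N18.3"}
        assert lib.codes("ckd", Category.DIAGNOSES, "anemia") == {"D64.9", "D50.0"}

    def test_unknown_condition_lists_available(self):
        lib = ConceptLibrary(
            entries=self._entries(), cohort_entry={"ckd": [("ICD10", "N18.3")]}
        )
        with pytest.raises(KeyError, match="ckd"):
            lib.cohort_codes("copd")

    def test_find_category(self):
        lib = ConceptLibrary(
            entries=self._entries(), cohort_entry={"ckd": [("ICD10", "N18.3")]}
        )
        assert lib.find_category("ckd", "anemia") is Category.DIAGNOSES
        with pytest.raises(KeyError):
            lib.find_category("ckd", "iron")


def test_dataset_validate_rejects_duplicate_record_ids():
    e = CodedEventRecord(
        patient_id="p1", record_id="E1", event_date=dt.date(2018, 1, 1),
        domain=EventDomain.DIAGNOSIS, code="X",
    )
    ds = CdmDataset(events=[e, e])
    with pytest.raises(ValueError, match="duplicate record_id"):
        ds.validate()
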