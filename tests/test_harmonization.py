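import datetime as dt
import random
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdmaudit.harmonization import (
    CrosswalkContext,
    Direction,
    DiscrepancyFinding,
    Disposition,
    IssueType,
    RecordDomain,
    Severity,
    SEVERITIES_BY_ISSUE,
    classify_discrepancy,
    enumerate_crosswalk,
    harmonization_report,
    impact_counts,
    mapping_cardinality,
    normalize_name,
    result_distribution_outlier,
    select_top_names,
)
from cdmaudit.model import CdmDataset

from conftest import lab, order


class TestNormalizeName:
    def test_dose_and_form_words_go_to_attributes(self):
        nn = normalize_name("Lisinopril 5 mg tablet")
        assert nn.ingredient_tokens == {"lisinopril"}
        assert nn.attribute_tokens == {"5", "mg", "tablet"}

    def test_empty_input(self):
        nn = normalize_name("")
        assert nn.is_empty and not nn.all_tokens

    def test_meter_and_point_of_care_variants_stay_distinct(self):
        a = normalize_name("GLUCOSE [METER]")
        b = normalize_name("GLUCOSE [POINT-OF-CARE]")
        assert a.key != b.key

    @given(st.text(max_size=30))
    def test_key_normalization_is_idempotent(self, raw):
        once = normalize_name(raw)
        assert normalize_name(once.key).key == once.key


class TestSelectTopNames:
    def _records(self, spec):
        out, i = [], 0
        for name, count in spec.items():
            for _ in range(count):
                out.append(order(f"p{i}", f"r{i}", name))
                i += 1
        return out

    def test_top_two_by_volume(self):
        records = self._records({"A": 5, "B": 3, "C": 1})
        sel = select_top_names(records, n=2)
        assert sel.names == ["A", "B"]
        assert len(sel.records) == 8

    def test_tie_broken_lexicographically(self):
        records = self._records({"B": 3, "A": 3})
        assert select_top_names(records, n=1).names == ["A"]

    def test_n_larger_than_distinct_names(self):
        records = self._records({"A": 1, "B": 1})
        assert len(select_top_names(records, n=200).names) == 2

    def test_null_names_counted_separately(self):
        records = self._records({"A": 2}) + [order("p9", "r9", "")]
        sel = select_top_names(records, n=5)
        assert sel.names == ["A"] and sel.n_null_name_records == 1

    def test_deterministic_under_record_shuffle(self):
        records = self._records({"A": 4, "B": 4, "C": 2, "D": 1})
        baseline = select_top_names(records, n=3).names
        rng = random.Random(7)
        for _ in range(5):
            rng.shuffle(records)
            assert select_top_names(records, n=3).names == baseline


class TestMappingCardinality:
    def test_hand_enumerated_example(self):
        records = [
            order("p1", "r1", "A", "c1"),
            order("p2", "r2", "B", "c1"),
            order("p3", "r3", "B", "c2"),
            order("p4", "r4", "C", None),
        ]
        stats = mapping_cardinality(records, Direction.CODES_PER_NAME)
        assert sorted(stats.per_key.values()) == [0, 1, 2]
        assert (stats.median, stats.minimum, stats.maximum) == (1, 0, 2)
        rev = mapping_cardinality(records, Direction.NAMES_PER_CODE)
        assert sorted(rev.per_key.values()) == [1, 2]

    def test_single_pair(self):
        stats = mapping_cardinality([order("p", "r", "A", "c")], Direction.CODES_PER_NAME)
        assert (stats.median, stats.minimum, stats.maximum) == (1, 1, 1)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            mapping_cardinality([], Direction.CODES_PER_NAME)

    def test_oracle_equivalence_against_brute_force(self):
        """Medians/extremes equal a naive per-key distinct recount."""
        rng = random.Random(11)
        records = [
            order(f"p{rng.randrange(40)}", f"r{i}",
                  f"name{rng.randrange(25)}",
                  None if rng.random() < 0.1 else f"c{rng.randrange(20)}")
            for i in range(600)
        ]
        stats = mapping_cardinality(records, Direction.CODES_PER_NAME)
        by_name = {}
        for r in records:
            by_name.setdefault(normalize_name(r.raw_name).key, set())
            if r.code is not None:
                by_name[normalize_name(r.raw_name).key].add(r.code)
        counts = [len(v) for v in by_name.values()]
        assert stats.median == statistics.median(counts)
        assert stats.minimum == min(counts) and stats.maximum == max(counts)
        assert stats.per_key == {k: len(v) for k, v in by_name.items()}


class TestEnumerateCrosswalk:
    def test_multi_mapped_name(self):
        records = [order(f"p{i}", f"r{i}", "Heparin", "c1") for i in range(10)]
        records += [order(f"q{i}", f"s{i}", "Heparin", "c2") for i in range(5)]
        entries = enumerate_crosswalk(records)
        assert len(entries) == 2
        assert all(e.multi_code for e in entries)
        assert {e.n_records for e in entries} == {10, 5}

    def test_null_mapped_names(self):
        records = [order(f"p{i}", f"r{i}", f"name {i}", None) for i in range(11)]
        entries = enumerate_crosswalk(records)
        assert len(entries) == 11
        assert all(e.null_mapped for e in entries)

    def test_record_totals_partition(self):
        rng = random.Random(3)
        records = [
            order(f"p{rng.randrange(10)}", f"r{i}", f"n{rng.randrange(6)}",
                  f"c{rng.randrange(5)}")
            for i in range(200)
        ]
        entries = enumerate_crosswalk(records)
        assert sum(e.n_records for e in entries) == len(records)
        assert all(e.n_patients <= e.n_records for e in entries)


def _classify(records, ref, target_name, code):
    entries = enumerate_crosswalk(records)
    context = CrosswalkContext(entries)
    entry = next(
        e
        for e in entries
        if e.name_key == normalize_name(target_name).key and e.code == code
    )
    return classify_discrepancy(entry, ref, context)


class TestClassifyDiscrepancy:
    """Severity cascade on hand-built crosswalk situations."""

    def test_null_code_is_critical(self, toy_terminology):
        records = [order("p", "r", "heparin", None)]
        f = _classify(records, toy_terminology, "heparin", None)
        assert f.issue_type is IssueType.NULL_CODE and f.severity is Severity.CRITICAL

    def test_wrong_drug_code_is_critical(self, toy_terminology):
        # name and code description share no ingredient
        records = [order("p", "r", "Heparin", "103418")]  # lidocaine cream code
        f = _classify(records, toy_terminology, "Heparin", "103418")
        assert f.issue_type is IssueType.INGREDIENT_MISMATCH
        assert f.severity is Severity.CRITICAL

    def test_generic_name_with_brand_code_is_moderate(self, toy_terminology):
        records = [order("p", "r", "lisinopril 5 mg tablet", "206765")]
        f = _classify(records, toy_terminology, "lisinopril 5 mg tablet", "206765")
        assert f.issue_type is IssueType.GENERIC_NAME_BRAND_CODE
        assert f.severity is Severity.MODERATE

    def test_brand_name_with_generic_code_is_moderate(self, toy_terminology):
        records = [order("p", "r", "Zestril 5 mg tablet", "311354")]
        f = _classify(records, toy_terminology, "Zestril 5 mg tablet", "311354")
        assert f.issue_type is IssueType.BRAND_NAME_GENERIC_CODE
        assert f.severity is Severity.MODERATE

    def test_single_ingredient_name_multi_ingredient_code_is_critical(
        self, toy_terminology
    ):
        records = [order("p", "r", "Oxycodone", "1049221")]
        f = _classify(records, toy_terminology, "Oxycodone", "1049221")
        assert f.issue_type is IssueType.SINGLE_INGREDIENT_TO_MULTI_CODE
        assert f.severity is Severity.CRITICAL

    def test_multi_ingredient_name_single_code_is_critical(self, toy_terminology):
        records = [order("p", "r", "acetaminophen-oxycodone 325-2.5 mg tablet", "1658717")]
        f = _classify(
            records, toy_terminology, "acetaminophen-oxycodone 325-2.5 mg tablet",
            "1658717",
        )
        assert f.issue_type is IssueType.MULTI_INGREDIENT_TO_SINGLE_CODE
        assert f.severity is Severity.CRITICAL

    def test_attributed_name_with_ingredient_code_is_major(self, toy_terminology):
        records = [order("p", "r", "lisinopril 5 mg tablet", "29046")]
        f = _classify(records, toy_terminology, "lisinopril 5 mg tablet", "29046")
        assert f.issue_type is IssueType.INGREDIENT_LEVEL_CODE
        assert f.severity is Severity.MAJOR

    def test_bare_name_with_granular_code_is_major(self, toy_terminology):
        records = [order("p", "r", "lisinopril", "311354")]
        f = _classify(records, toy_terminology, "lisinopril", "311354")
        assert f.issue_type is IssueType.OVERGRANULAR_CODE
        assert f.severity is Severity.MAJOR

    def test_mixture_split_is_informational_minor(self, toy_terminology):
        # one mixture-style name mapped to two single-ingredient codes whose
        # ingredients both appear in the name
        records = [
            order("p", "r1", "heparin-lidocaine admixture", "1658717"),
            order("p", "r2", "heparin-lidocaine admixture", "103418"),
        ]
        f = _classify(records, toy_terminology, "heparin-lidocaine admixture", "1658717")
        assert f.issue_type is IssueType.MIXTURE_MULTI_CODE
        assert f.severity is Severity.MINOR

    @pytest.mark.parametrize(
        "name", ["12345", "ZZ IMS template", "Non-formulary medication"]
    )
    def test_uninformative_names(self, toy_terminology, name):
        records = [order("p", "r", name, "311354")]
        f = _classify(records, toy_terminology, name, "311354")
        assert f.issue_type is IssueType.UNINFORMATIVE_NAME
        assert f.severity is Severity.UNKNOWN

    def test_wrong_lab_code_is_critical(self, toy_terminology):
        records = [lab("p", "r", "Chloride", "2160-0")]  # creatinine code
        f = _classify(records, toy_terminology, "Chloride", "2160-0")
        assert f.issue_type is IssueType.LAB_TEST_MISMATCH
        assert f.severity is Severity.CRITICAL

    def test_poc_name_sharing_clinical_lab_code_is_minor(self, toy_terminology):
        records = [
            lab("p", "r1", "Glucose Lvl", "2345-7"),
            lab("p", "r2", "Glucose, POCT", "2345-7"),
        ]
        f = _classify(records, toy_terminology, "Glucose, POCT", "2345-7")
        assert f.issue_type is IssueType.POC_CLINICAL_SHARED_CODE
        assert f.severity is Severity.MINOR
        # the non-POC sibling carries the same component; it is not flagged
        sibling = _classify(records, toy_terminology, "Glucose Lvl", "2345-7")
        assert isinstance(sibling, Disposition) and sibling.status == "ok"

    def test_count_and_percent_variants_sharing_code_is_critical(self, toy_terminology):
        records = [
            lab("p", "r1", "EOS ABS", "711-2"),
            lab("p", "r2", "EOS PCT AUTO", "711-2"),
        ]
        f = _classify(records, toy_terminology, "EOS ABS", "711-2")
        assert f.issue_type is IssueType.SHARED_CODE_DIFFERENT_COMPONENTS
        assert f.severity is Severity.CRITICAL

    def test_unknown_code_is_unassessable(self, toy_terminology):
        records = [order("p", "r", "heparin", "999999")]
        outcome = _classify(records, toy_terminology, "heparin", "999999")
        assert isinstance(outcome, Disposition)
        assert outcome.status == "unassessable"

    def test_issue_severity_map_covers_all_severities(self):
        covered = set().union(*SEVERITIES_BY_ISSUE.values())
        assert covered == set(Severity)


class TestResultDistributionOutlier:
    def _labs(self, name, code, values, offset=0):
        return [
            lab(f"p{i}", f"{name}-{i}", name, code, v + offset)
            for i, v in enumerate(values)
        ]

    def test_identical_distributions_not_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, 200)
        records = self._labs("A", "c", base) + self._labs("B", "c", base)
        assert result_distribution_outlier(records) == []

    def test_shifted_distribution_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, 200).tolist()
        records = self._labs("A", "c", base) + self._labs("B", "c", base, offset=100)
        flagged = result_distribution_outlier(records)
        # with only two names the fence is symmetric, so both flag; the
        # shifted name must be among them
        assert ("c", "B") in [(code, name) for code, name, *_ in flagged]

    def test_single_name_under_code_skipped(self):
        records = self._labs("A", "c", list(range(100)))
        assert result_distribution_outlier(records) == []


class TestImpactCounts:
    def _finding(self, entry):
        return DiscrepancyFinding(
            entry=entry, issue_type=IssueType.NULL_CODE,
            severity=Severity.CRITICAL, rationale="t",
        )

    def test_fraction_of_domain(self):
        domain = [order(f"p{i}", f"r{i}", "X", None) for i in range(5)]
        domain += [order(f"q{i}", f"s{i}", "Y", "c") for i in range(95)]
        entry = enumerate_crosswalk(domain[:5])[0]
        f = impact_counts(self._finding(entry), domain)
        assert f.n_records == 5 and f.fraction_of_domain_records == pytest.approx(0.05)

    def test_same_name_different_codes_have_disjoint_counts(self):
        domain = [order(f"p{i}", f"r{i}", "X", "c1") for i in range(6)]
        domain += [order(f"q{i}", f"s{i}", "X", "c2") for i in range(4)]
        entries = enumerate_crosswalk(domain)
        totals = sum(
            impact_counts(self._finding(e), domain).n_records for e in entries
        )
        assert totals == 10


class TestHarmonizationReport:
    def test_clean_small_dataset_has_no_findings(self, small_bundle):
        dataset, ref, _lib = small_bundle
        report = harmonization_report(dataset, ref, n=200)
        severities = {f.severity for f in report.findings}
        assert Severity.CRITICAL not in severities
        assert Severity.MAJOR not in severities

    def test_empty_domain_noted_without_breaking_others(self, small_bundle):
        dataset, ref, _lib = small_bundle
        trimmed = CdmDataset(
            partner_label=dataset.partner_label,
            labs=dataset.labs, orders=dataset.orders,
            administrations=[], events=dataset.events,
        )
        report = harmonization_report(trimmed, ref, n=50)
        assert RecordDomain.ADMINISTRATIONS in report.absent_domains
        assert (Direction.CODES_PER_NAME, RecordDomain.ORDERS) in report.cardinality

    def test_crosswalk_totals_match_selected_records(self, small_bundle):
        dataset, ref, _lib = small_bundle
        report = harmonization_report(dataset, ref, n=50)
        sel = report.selections[RecordDomain.ORDERS]
        entries = enumerate_crosswalk(sel.records, domain=RecordDomain.ORDERS)
        assert sum(e.n_records for e in entries) == len(sel.records)
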