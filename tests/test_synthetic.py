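import copy

import pytest

from cdmaudit.harmonization import (
    IssueType,
    RecordDomain,
    enumerate_crosswalk,
    harmonization_report,
    select_top_names,
)
from cdmaudit.model import Category
from cdmaudit.synthetic import (
    ClassRecall,
    ConceptSpec,
    ConditionSpec,
    GeneratorConfig,
    GroundTruthLedger,
    IssueClass,
    IssueSpec,
    LedgerEntry,
    RecallResult,
    default_conditions,
    generate_clean,
    inject_issues,
    ledger_recall,
)


class TestGeneratorConfig:
    def test_invalid_prevalence_rejected_before_generation(self):
        conds = default_conditions()
        conds[0].prevalence = 1.5
        with pytest.raises(ValueError, match="prevalence"):
            generate_clean(GeneratorConfig(seed=0, n_patients=10, conditions=conds))

    def test_negative_rate_rejected(self):
        conds = [
            ConditionSpec(
                label="x", prevalence=0.5,
                concepts=[ConceptSpec(label="a", category=Category.DIAGNOSES, rate=-1)],
            )
        ]
        with pytest.raises(ValueError, match="rate"):
            generate_clean(GeneratorConfig(seed=0, n_patients=10, conditions=conds))

    def test_non_contiguous_years_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            generate_clean(GeneratorConfig(seed=0, n_patients=10, years=(2016, 2018)))


class TestGenerateClean:
    def test_deterministic_given_seed(self):
        a, ref_a, lib_a = generate_clean(GeneratorConfig(seed=9, n_patients=150))
        b, ref_b, lib_b = generate_clean(GeneratorConfig(seed=9, n_patients=150))
        assert a.labs == b.labs
        assert a.orders == b.orders
        assert a.administrations == b.administrations
        assert a.events == b.events
        assert sorted(ref_a.concepts) == sorted(ref_b.concepts)
        assert lib_a.entries == lib_b.entries

    def test_different_seeds_differ(self):
        a, *_ = generate_clean(GeneratorConfig(seed=9, n_patients=150))
        b, *_ = generate_clean(GeneratorConfig(seed=10, n_patients=150))
        assert a.orders != b.orders

    def test_record_ids_unique(self, small_bundle):
        dataset, _ref, _lib = small_bundle
        dataset.validate()

    def test_every_code_resolves_in_terminology(self, small_bundle):
        dataset, ref, _lib = small_bundle
        assert all(r.code in ref for r in dataset.orders)
        assert all(r.code in ref for r in dataset.administrations)
        assert all(r.code in ref for r in dataset.labs)

    def test_names_map_one_to_one(self, small_bundle):
        dataset, _ref, _lib = small_bundle
        for records in (dataset.orders, dataset.administrations, dataset.labs):
            entries = enumerate_crosswalk(records)
            assert all(not e.multi_code and not e.multi_name for e in entries)


class TestInjectIssues:
    def test_empty_spec_list_is_a_no_op(self, small_bundle):
        dataset, ref, _lib = small_bundle
        before = copy.deepcopy(dataset.orders)
        mutated, ledger = inject_issues(dataset, ref, [], seed=0)
        assert mutated.orders == before and ledger.entries == []

    def test_unknown_target_errors(self, small_bundle):
        dataset, ref, _lib = small_bundle
        with pytest.raises(ValueError, match="not found"):
            inject_issues(
                dataset, ref,
                [IssueSpec(IssueClass.NULL_CODE, "no such name", RecordDomain.ORDERS)],
                seed=0,
            )

    def test_stream_issue_requires_library(self, small_bundle):
        dataset, ref, _lib = small_bundle
        with pytest.raises(ValueError, match="library"):
            inject_issues(
                dataset, ref,
                [IssueSpec(IssueClass.DROP_ORDER_STREAM, "ckd/iron")], seed=0,
            )

    def test_null_code_injection_yields_null_mapped_entries(self):
        dataset, ref, _lib = generate_clean(GeneratorConfig(seed=21, n_patients=400))
        sel = select_top_names(dataset.orders, n=11, domain=RecordDomain.ORDERS)
        specs = [
            IssueSpec(IssueClass.NULL_CODE, name, RecordDomain.ORDERS)
            for name in sel.names
        ]
        dataset, ledger = inject_issues(dataset, ref, specs, seed=21)
        top = select_top_names(dataset.orders, n=200, domain=RecordDomain.ORDERS)
        entries = enumerate_crosswalk(top.records)
        null_names = {e.name_key for e in entries if e.null_mapped}
        assert len(null_names) == 11

    def test_injection_conservation(self, injected_bundle):
        """Record counts change exactly as the ledger states."""
        ledger: GroundTruthLedger = injected_bundle["ledger"]
        dataset = injected_bundle["dataset"]
        by_class = ledger.by_class()
        # mixture splits: removed originals and added one record per ingredient
        mix = by_class[IssueClass.MIXTURE_MULTI_CODE][0]
        originals = [i for i in mix.affected_record_ids if "x" not in i]
        added = [i for i in mix.affected_record_ids if "x" in i]
        assert len(added) == 2 * len(originals)
        admin_ids = {r.record_id for r in dataset.administrations}
        assert set(added) <= admin_ids
        assert not (set(originals) & admin_ids)
        # dropped orders are gone
        drop = by_class[IssueClass.DROP_ORDER_STREAM][0]
        order_ids = {r.record_id for r in dataset.orders}
        assert not (set(drop.affected_record_ids) & order_ids)

    def test_clean_dataset_audit_is_silent_after_reaudit(self, injected_bundle):
        """Only injected targets surface: every finding maps to the ledger."""
        recall: RecallResult = injected_bundle["recall"]
        assert recall.false_positive_keys == []


class TestLedgerRecall:
    def _ledger(self, n):
        return GroundTruthLedger(
            entries=[
                LedgerEntry(
                    issue_class=IssueClass.DECAY_ADMIN_RATIO, target=f"c/m{i}",
                    detect_key=f"c/m{i}", domain=None, affected_record_ids=[],
                )
                for i in range(n)
            ]
        )

    def test_no_findings_nonempty_ledger_gives_zero(self):
        res = ledger_recall(self._ledger(2), findings=[], ratio_flags={})
        assert res.overall_recall == 0.0

    def test_three_of_four_drift_flags_gives_075(self):
        flags = {("c", f"m{i}"): {"drift"} for i in range(3)}
        res = ledger_recall(self._ledger(4), findings=[], ratio_flags=flags)
        assert res.overall_recall == pytest.approx(0.75)
        assert res.per_class[IssueClass.DECAY_ADMIN_RATIO].recall == pytest.approx(0.75)

    def test_empty_ledger_gives_perfect_scores(self):
        res = ledger_recall(GroundTruthLedger(), findings=[])
        assert res.overall_recall == 1.0 and res.precision == 1.0
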