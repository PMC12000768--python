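import datetime as dt

import pytest

from cdmaudit.completeness import (
    AnomalyThresholds,
    DatasetIndex,
    RatioPoint,
    StratifiedCount,
    Stratifier,
    admin_order_ratio,
    build_cohort,
    concept_counts,
    detect_anomalies,
    provenance_percentage,
    round_half_up_percent,
)
from cdmaudit.model import (
    Category,
    CdmDataset,
    CodedEventRecord,
    ConceptLibrary,
    EncounterType,
    EventDomain,
    MedAdminRecord,
    MedOrderRecord,
    Provenance,
)


def dx(pid, rid, code, year, prov=Provenance.BILLING, enc=EncounterType.OUTPATIENT):
    return CodedEventRecord(
        patient_id=pid, record_id=rid, event_date=dt.date(year, 6, 1),
        domain=EventDomain.DIAGNOSIS, code=code, provenance=prov, encounter_type=enc,
    )


@pytest.fixture()
def tiny_library():
    return ConceptLibrary(
        entries={
            "ckd": {
                Category.DIAGNOSES: {"anemia": [("ICD10", "D64.9")]},
                Category.MEDICATIONS: {"iron": [("RXNORM", "5555")]},
            }
        },
        cohort_entry={"ckd": [("ICD10", "N18.3")]},
    )


@pytest.fixture()
def tiny_dataset():
    ds = CdmDataset(partner_label="tiny")
    # p1: cohort member 2016 and 2017; anemia in 2016 from both streams
    ds.events = [
        dx("p1", "e1", "N18.3", 2016),
        dx("p1", "e2", "N18.3", 2017),
        dx("p1", "e3", "D64.9", 2016, prov=Provenance.ORDERED),
        dx("p1", "e4", "D64.9", 2016, prov=Provenance.BILLING),
        # p2: cohort member 2016 only, two qualifying records (counted once)
        dx("p2", "e5", "N18.3", 2016),
        dx("p2", "e6", "N18.3", 2016),
        dx("p2", "e7", "D64.9", 2016, prov=Provenance.BILLING),
        # p3: anemia but never a cohort-entry diagnosis -> outside cohort
        dx("p3", "e8", "D64.9", 2016),
    ]
    ds.orders = [
        MedOrderRecord("p1", "o1", dt.date(2016, 2, 1), "iron tablet", "5555"),
        MedOrderRecord("p1", "o2", dt.date(2016, 3, 1), "iron tablet", "5555"),
        MedOrderRecord("p2", "o3", dt.date(2016, 4, 1), "iron tablet", "5555"),
        MedOrderRecord("p1", "o4", dt.date(2017, 4, 1), "iron tablet", "5555"),
    ]
    ds.administrations = [
        MedAdminRecord("p1", "a1", dt.date(2016, 2, 2), "iron tablet", "5555"),
        MedAdminRecord("p2", "a2", dt.date(2016, 4, 2), "iron tablet", "5555"),
        MedAdminRecord("p1", "a3", dt.date(2017, 4, 2), "iron tablet", "5555"),
    ]
    return ds


class TestBuildCohort:
    def test_incident_membership_by_calendar_year(self, tiny_dataset, tiny_library):
        cohort = build_cohort(tiny_dataset, tiny_library, "ckd", years=(2016, 2017))
        assert cohort.members[2016] == {"p1", "p2"}
        assert cohort.members[2017] == {"p1"}

    def test_prevalent_membership_persists(self, tiny_dataset, tiny_library):
        cohort = build_cohort(
            tiny_dataset, tiny_library, "ckd", years=(2016, 2017),
            membership="prevalent",
        )
        assert cohort.members[2017] == {"p1", "p2"}

    def test_unknown_condition_errors_with_available(self, tiny_dataset, tiny_library):
        with pytest.raises(KeyError, match="ckd"):
            build_cohort(tiny_dataset, tiny_library, "copd", years=(2016, 2017))

    def test_prefix_code_match_catches_hierarchical_descendants(
        self, tiny_dataset, tiny_library
    ):
        lib = ConceptLibrary(
            entries=tiny_library.entries,
            cohort_entry={"ckd": [("ICD10", "N18")]},  # parent of N18.3
        )
        exact = build_cohort(tiny_dataset, lib, "ckd", years=(2016, 2017))
        assert exact.members[2016] == set()
        prefix = build_cohort(
            tiny_dataset, lib, "ckd", years=(2016, 2017), code_match="prefix"
        )
        assert prefix.members[2016] == {"p1", "p2"}


class TestConceptCounts:
    def test_patient_in_both_strata_counted_once_in_total(
        self, tiny_dataset, tiny_library
    ):
        cohort = build_cohort(tiny_dataset, tiny_library, "ckd", years=(2016, 2017))
        counts = concept_counts(
            tiny_dataset, cohort, tiny_library, "ckd", "anemia",
            stratifier=Stratifier.PROVENANCE,
        )
        y2016 = {c.stratum: c for c in counts if c.year == 2016}
        assert y2016["ordered"].concept_total == 2  # p1 and p2, p1 in both streams
        assert y2016["ordered"].n_patients == 1
        assert y2016["billing"].n_patients == 2
        assert y2016["claim"].n_patients == 0

    def test_no_matching_records_gives_zero_total_and_null_pct(
        self, tiny_dataset, tiny_library
    ):
        cohort = build_cohort(tiny_dataset, tiny_library, "ckd", years=(2016, 2017))
        counts = provenance_percentage(
            concept_counts(
                tiny_dataset, cohort, tiny_library, "ckd", "anemia",
                stratifier=Stratifier.NONE, years=(2017,),
            )
        )
        assert counts[0].concept_total == 0 and counts[0].pct is None

    def test_medications_pool_orders_and_administrations(
        self, tiny_dataset, tiny_library
    ):
        cohort = build_cohort(tiny_dataset, tiny_library, "ckd", years=(2016, 2017))
        counts = concept_counts(
            tiny_dataset, cohort, tiny_library, "ckd", "iron",
            stratifier=Stratifier.NONE,
        )
        assert {c.year: c.concept_total for c in counts} == {2016: 2, 2017: 1}

    def test_medications_reject_provenance_stratifier(self, tiny_dataset, tiny_library):
        cohort = build_cohort(tiny_dataset, tiny_library, "ckd", years=(2016, 2017))
        with pytest.raises(ValueError, match="none"):
            concept_counts(
                tiny_dataset, cohort, tiny_library, "ckd", "iron",
                stratifier=Stratifier.PROVENANCE,
            )

    def test_stratum_bounded_by_concept_total(self, small_bundle):
        dataset, _ref, library = small_bundle
        cohort = build_cohort(dataset, library, "chronic_kidney_disease")
        counts = concept_counts(
            dataset, cohort, library, "chronic_kidney_disease", "anemia"
        )
        for c in counts:
            assert 0 <= c.n_patients <= c.concept_total <= c.cohort_total

    def test_brute_force_oracle_equivalence(self, tiny_dataset, tiny_library):
        """Stratified counts equal a naive nested-loop recount."""
        cohort = build_cohort(tiny_dataset, tiny_library, "ckd", years=(2016, 2017))
        counts = concept_counts(
            tiny_dataset, cohort, tiny_library, "ckd", "anemia",
            stratifier=Stratifier.PROVENANCE,
        )
        for c in counts:
            naive = set()
            for e in tiny_dataset.events:
                if (
                    e.domain is EventDomain.DIAGNOSIS
                    and e.code.upper() == "D64.9"
                    and e.event_date.year == c.year
                    and e.provenance.value == c.stratum
                    and e.patient_id in cohort.members[c.year]
                ):
                    naive.add(e.patient_id)
            assert c.n_patients == len(naive)


class TestProvenancePercentage:
    @pytest.mark.parametrize(
        "n,total,expected",
        [
            (3292, 5210, 63),
            (4934, 5210, 95),
            (37, 987, 4),
            (973, 987, 99),
            (73, 140, 52),
            (1071, 1249, 86),
            (202, 283, 71),
            (82, 613, 13),
            (5, 5, 100),
            (0, 7, 0),
        ],
    )
    def test_round_half_up_integer_percent(self, n, total, expected):
        assert round_half_up_percent(n, total) == expected

    def test_zero_denominator_gives_none(self):
        assert round_half_up_percent(3, 0) is None


class TestRatio:
    def _point(self, year, n_admin, n_orders):
        return RatioPoint(
            condition="c", concept="m", year=year,
            n_admin_records=n_admin, n_order_records=n_orders,
        )

    def test_ratio_arithmetic(self):
        assert self._point(2016, 100, 100).ratio_pct == pytest.approx(100.0)
        assert self._point(2016, 25, 100).ratio_pct == pytest.approx(25.0)

    def test_zero_orders_undefined_and_flagged(self):
        p = self._point(2016, 10, 0)
        assert p.ratio_pct is None and "zero_orders" in p.flags

    def test_series_from_dataset(self, tiny_dataset, tiny_library):
        cohort = build_cohort(tiny_dataset, tiny_library, "ckd", years=(2016, 2017))
        series = admin_order_ratio(
            tiny_dataset, cohort, tiny_library, "ckd", "iron"
        )
        assert [(p.year, p.n_order_records, p.n_admin_records) for p in series] == [
            (2016, 3, 2), (2017, 1, 1),
        ]


class TestDetectAnomalies:
    def _series(self, ratios, n_orders=100):
        return [
            RatioPoint(
                condition="c", concept="m", year=2016 + i,
                n_admin_records=int(r * n_orders / 100), n_order_records=n_orders,
            )
            for i, r in enumerate(ratios)
        ]

    def test_declining_series_is_drift_flagged(self):
        series = detect_anomalies(self._series([100, 80, 50, 25]))
        assert all("drift" in p.flags for p in series)

    def test_extreme_high_ratio_flagged(self):
        series = detect_anomalies(self._series([100, 9000]))
        assert "extreme" in series[1].flags

    def test_constant_series_not_flagged(self):
        series = detect_anomalies(self._series([100, 100, 100, 100]))
        assert all(not p.flags for p in series)

    def test_small_count_guard(self):
        series = detect_anomalies(self._series([100, 9000], n_orders=5))
        assert all("extreme" not in p.flags and "drift" not in p.flags for p in series)

    def test_zero_orders_with_many_administrations_is_extreme(self):
        p = RatioPoint(condition="c", concept="m", year=2016,
                       n_admin_records=500, n_order_records=0)
        (out,) = detect_anomalies([p])
        assert {"zero_orders", "extreme"} <= out.flags

    def test_invariant_to_uniform_rescaling(self):
        a = detect_anomalies(self._series([100, 80, 50, 25], n_orders=100))
        b = detect_anomalies(self._series([100, 80, 50, 25], n_orders=400))
        assert [p.flags for p in a] == [p.flags for p in b]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            AnomalyThresholds(extreme_low_pct=150)
        with pytest.raises(ValueError):
            AnomalyThresholds(drift_factor=0.5)


def test_stratified_count_invariants_enforced():
    with pytest.raises(ValueError):
        StratifiedCount(
            condition="c", category=Category.DIAGNOSES, concept="x", year=2016,
            stratifier=Stratifier.NONE, stratum="all",
            n_patients=5, concept_total=3, cohort_total=10,
        )
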