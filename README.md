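# cdmaudit

Data-quality audits for electronic-health-record extracts harmonized into a
PCORnet-style common data model (CDM), for data-curation teams and
real-world-data researchers who need to know whether a partner's CDM tables
can be trusted before a study runs against them.

Two questions drive the package:

1. **Harmonization** — were raw, source-system laboratory and medication
   names mapped faithfully to reference terminologies (LOINC-style lab
   codes, RxNorm-style drug codes)?
2. **Completeness** — are the records for a clinical concept all there,
   judged by comparing complementary data streams: diagnosis/procedure
   records by *provenance* (clinician-entered vs billing vs claims vs
   derived), and medication *administrations* against *orders* over time?

## The statistics at the core

**Mapping cardinality.** For the top-*N* (default 200) raw names by record
volume in each domain, the audit reports min/median/max of the number of
distinct codes per raw name, and of raw names per code. For a
well-harmonized table both medians are ~1; a name mapped only to null codes
contributes 0, which is how a minimum of 0 arises.

**Severity-graded findings.** Every distinct (raw name, code) pair is
passed through a first-match-wins cascade that compares the ingredients of
the assigned drug code with the tokens of the medication name (and the lab
code's component with the raw lab name), then grades each discrepancy:

| severity | example issue |
|---|---|
| critical | name/code ingredient mismatch; single-ingredient name on a multi-ingredient code (or vice versa); null code; count-vs-percent lab variants sharing one code |
| major    | ingredient-level code where the name carries strength/form; code more granular than the name supports |
| moderate | generic name on a branded code (or vice versa); different components sharing a code |
| minor    | point-of-care test sharing a clinical-lab code; outlying result distribution under a shared code |
| unknown  | uninformative name (integer string, "ZZ ... TEMPLATE", "non-formulary") |

Each finding carries record/patient impact counts measured on the full
(pre-top-N) table.

**Provenance-stratified completeness.** For each condition cohort
(patients with a qualifying diagnosis in a calendar year) and each clinical
concept, the audit counts distinct patients with a matching record per
year and per provenance stratum, reporting integer percentages
(round-half-up) of the concept denominator. A patient in several streams
counts once in the denominator and once in each stratum, so a stratum
percentage is exactly the share of concept patients a single-provenance
extract would retain.

**Administration/order ratio.** For each medication concept,
`100 × administrations / orders` per year. The ratio should be stable; a
series whose max/min ratio reaches the drift factor (default 2) is
drift-flagged, and points at or beyond the extreme bounds (defaults 300%
and 10%) — or with administrations but no orders at all — are
extreme-flagged, subject to a small-count guard (default 20 orders).

Because real CDM extracts cannot be shipped, `cdmaudit.synthetic` generates
datasets with this exact structure — per-concept event rates, independent
per-patient-year provenance draws, configurable yearly ratio schedules, and
a jointly generated toy terminology — and injects every error class above
with a ground-truth ledger, so both audits are scored by recall/precision
against known truth.

## Worked example

`examples/01_simulate_and_audit.py` generates 1 000 synthetic patients and
audits them:

```
records: {'labs': 12307, 'orders': 7767, 'administrations': 7767, 'diagnoses': 7407, 'procedures': 3464}
         direction                     domain median (min, max)
Codes per raw name          Medication orders          1 (1, 1)
Codes per raw name Medication administrations          1 (1, 1)
Codes per raw name         Laboratory results          1 (1, 1)
Raw names per code          Medication orders          1 (1, 1)
Raw names per code Medication administrations          1 (1, 1)
Raw names per code         Laboratory results          1 (1, 1)
findings by severity: {'critical': 0, 'major': 0, 'moderate': 0, 'minor': 0, 'unknown': 0}
```

Every cardinality cell is `1 (1, 1)` and there are no findings: clean data
is the audit's null result. `examples/02_error_injection.py` then injects
one issue per error class and recovers all of them:

```
issue                              severity   raw name
generic_name_brand_code            moderate   KUFIGAIN 100 MG CAPSULE
ingredient_level_code              major      LINOTIIN 500 MG CAPSULE
ingredient_mismatch                critical   ROMARAIN 25 MG SOLUTION
...
overall recall 1.00, precision 1.00
```

`examples/03_completeness_provenance.py` prints the provenance split for an
anemia concept in a chronic kidney disease cohort — e.g. in 2016, 244 of
250 concept patients (98%) appear in the billing stream but only 173 (69%)
in the clinician-entered stream, the kind of gap that makes a
single-provenance extract hazardous. `examples/04_ratio_anomalies.py`
shows a medication whose administration/order ratio decays 100% → 25%
(drift-flagged) and one whose orders were never loaded (extreme-flagged),
and writes the ratio plot.

A thin CLI wraps the same library calls:

```bash
cdmaudit simulate --out dp1 --seed 7 --n-patients 5000 --inject-defaults
cdmaudit harmonize --data dp1 --out audit --fail-on critical
cdmaudit completeness --data dp1 --out audit
cdmaudit report --data dp1 --out audit
```

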