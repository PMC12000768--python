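# Methods

## Scope and data model

The package audits delimited-text extracts of five CDM tables: laboratory
results, medication orders (prescribing), medication administrations,
diagnoses and procedures. Each lab/medication row carries the raw
(non-harmonized) source name next to the assigned reference code;
diagnosis/procedure rows carry a provenance (clinician-entered/"ordered",
billing, claim, derived; anything else coerces to unknown) and an encounter
type (outpatient, inpatient, emergency, other, unknown). Both coercions are
total, so stratified counts over either enum partition the records. Column
names default to PCORnet-style headers (RAW_LAB_NAME/LAB_LOINC,
RAW_RX_MED_NAME/RXNORM_CUI, RAW_MEDADMIN_MED_NAME/MEDADMIN_CODE,
DX/DX_ORIGIN, PX/PX_SOURCE, ENC_TYPE) and are fully remappable through a
dialect, because only the fields matter, not the serialization. Sentinel
no-information values ({"NI", "UN", "OT", ""}) normalize to null, except in
the provenance/encounter columns where "OT" is a meaningful value ("other")
and unrecognized values already coerce to unknown. Rows with unparseable
dates are dropped and counted, never silently repaired; all date logic uses
calendar years only.

Terminology references are deliberately toy-scale flat files rather than
real LOINC/RxNorm releases (which require licensing and downloads): each
lab code carries a description, component, specimen and a method flag
(clinical lab vs point of care); each drug code carries an ingredient list,
a granularity level (ingredient / clinical drug / branded drug) and
optionally a brand. The concept library is a declarative YAML mapping
condition → category (diagnoses, medications, procedures, labs) → concept →
code list, plus per-condition cohort-entry diagnosis codes.

## Harmonization audit

Auditing is restricted to the top *N* = 200 raw names per domain by record
count, selection preceding all statistics; ties break by ascending
lexicographic name so the output is deterministic regardless of record
order. Names differing only in case/punctuation merge; any other difference
(e.g. "GLUCOSE [METER]" vs "GLUCOSE [POINT-OF-CARE]") keeps names distinct,
since such variants often encode genuinely different tests.

Name normalization splits a raw name into ingredient tokens (substance
words) and attribute tokens (numerals, units, dose forms, routes — a
configurable stop list). Fidelity comparison is token-overlap-based, not
edit-distance-based, because overlap is auditable: a reviewer can see
exactly which token justified a finding. Lab-name matching is additionally
prefix-tolerant (a token of ≥3 characters matches a longer token it
prefixes) because raw lab names routinely abbreviate ("EOS" for
eosinophils); without this, abbreviated-but-correct mappings would be
graded as mismatches.

The classifier is a first-match-wins cascade, so each (name, code) pair
yields at most one finding and impact counts stay disjoint:

1. null code → critical;
2. uninformative-pattern name (all digits, "template", "non formulary",
   "zz" substrings) → unknown severity;
3. code absent from the reference → explicit "unassessable" disposition
   (counted separately, never silently dropped);
4. name sharing no token with either the domain vocabulary or the code
   description → uninformative (unknown);
5. drugs: mixture shadow check (one name mapped to several
   single-ingredient codes that jointly cover the name's ingredients →
   informational mixture note, minor) — this must precede the
   multi-ingredient rules or a legitimate inpatient-mixture split would
   always be graded critical; then multi-ingredient name on a
   single-ingredient code and the converse (both critical), ingredient
   disjointness (critical), ingredient-level code under an attributed name
   (major), over-granular code under a bare name (major), generic↔brand
   swaps (moderate);
6. labs: component mismatch (critical); point-of-care marker with a
   clinical-lab code or non-POC siblings (minor) — checked before the
   shared-code rule, with POC markers excluded from component comparison,
   so the clean sibling of a POC variant is not co-flagged; shared code
   with conflicting count/percent conventions (critical) or with different
   component tokens (moderate).

One taxonomy tension is surfaced rather than reconciled: the
single-ingredient-name → multi-ingredient-code pattern is graded
**critical** here (the code asserts exposure to an ingredient the name does
not support), although a narrative reading of such cases sometimes calls
them major; the severity map is a single declared standard and is
configurable.

The result-distribution screen flags a raw name sharing a code when its
median numeric result falls outside the pooled Tukey fence
(Q1 − 1.5·IQR, Q3 + 1.5·IQR) of the other names' results, with a minimum of
50 results per group. The fence is the least-assumption robust rule; with
only two names under a code the comparison is symmetric and both names may
flag, which is the honest outcome when no majority defines a reference.
Impact counts (records, patients, fraction of the domain) are always
measured on the full pre-top-N table.

## Completeness audit

Cohort membership is incident-in-year: a patient belongs to a condition's
year-Y cohort when they have ≥1 qualifying diagnosis dated in Y. This makes
yearly denominators vary the way published cohort tables do; a
prevalent-ever variant is available via `membership="prevalent"`. Concept
matching is exact string match after trimming and upper-casing.

For each concept-year the denominator is the number of distinct cohort
patients with ≥1 matching record that year; stratum numerators count
distinct patients with ≥1 record of that provenance (or encounter type) —
strata overlap by design. Percentages are integer round-half-up; the
machine-readable outputs also carry the raw counts. Medication concepts
pool orders ∪ administrations for the unstratified count; medications and
labs carry no provenance, so only the unstratified count is defined for
them and requesting otherwise is an error rather than a zero.

Ratio points use record counts (not patients) by default, with a
patient-count variant behind a flag. Flags: a series drift-flags when
max/min of the defined ratios reaches `drift_factor` (default 2.0); a point
extreme-flags at ≥ `extreme_high_pct` (default 300) or ≤ `extreme_low_pct`
(default 10). Points under `min_orders` (default 20) are exempt from both —
except a point with zero orders but ≥ `min_orders` administrations, which
is the unambiguous missing-orders pattern and is flagged extreme. The 300%
bound reflects the range where administration/order ratios stop being
explainable by multiple administrations per order; the low bound, drift
factor and guard are pragmatic defaults exposed in `AnomalyThresholds`.

### The bundled worked example

`cdmaudit/data/ckd_provenance_worked_example.csv` transcribes a published
rendering of provenance-stratified counts for a chronic kidney disease
cohort (diagnosis concepts at one data partner, procedure concepts at
another, 2016–2021). Feeding the printed counts through
`provenance_percentage` reproduces 79 of the 84 printed percentage cells
exactly under round-half-up; the remaining 5 cells disagree with *every*
deterministic rounding rule (half-up, half-even, truncation) by exactly one
point and are recorded in `INCONSISTENT_CELLS` as transcription-source
inconsistencies rather than forced to match.

## Synthetic data generator

The generator emulates the statistical structure the audits assume, and its
defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_patients | 10 000 | population size |
| years | 2016–2021 | calendar years, contiguous |
| conditions | 4 (hepatitis C 3%, CKD 12%, COPD 10%, PAH 2%) | prevalence-drawn cohorts with concept slates in all four categories |
| p_active | 0.9 | probability a cohort member has qualifying care in a year |
| p_ordered / p_billed | 0.65 / 0.95 | independent per-patient-concept-year provenance draws (claim/derived default 0) |
| concept rates | 0.05–2.0 /patient-year | Poisson event counts per active cohort patient |
| ratio schedule | 1.0 | target administrations per order, per year |
| terminology | 120 drug families × 3 granularities + 40 combos, 300 lab codes (10 POC) | generated jointly so every clean mapping resolves |
| background rates | 1.0 labs, 0.5 orders /patient-year | population-wide volume so the top-200 slate is realistic |

Provenance profiles are drawn once per (patient, concept, year) and shared
by that patient's events in the year. This choice makes patient-level
stratum proportions equal the configured probabilities (up to the
conditioning on having any record at all: billed ≈ 96–97% and ordered ≈
66% of concept patients at the defaults), which is what the
parameter-recovery tests check; per-event draws would inflate multi-event
patients' stratum membership and make the probabilities unrecoverable from
patient-level counts. Independent ordered/billing draws still produce the
realistic "patient appears in both streams" overlap.

Ratios ≤ 1 are realized by Bernoulli thinning of one administration per
order; ratios > 1 add Poisson(ratio − 1) extra administrations, since
ratios above 100% require multiple administrations per order. With the
default schedule of exactly 1.0 the clean ratio is exactly 100%, so clean
concepts can never false-flag. Dates are uniform within each year; the
audits only consume calendar years. All draws come from one
`numpy.random.default_rng(seed)` in fixed iteration order, so generation
and injection are fully deterministic given the seed.

Issue injection mutates a clean dataset and logs every affected record id
in a ground-truth ledger: code substitutions (wrong code, null code,
brand/ingredient-level/single↔multi swaps), mixture splits (one record per
ingredient-level code), renames (template/integer uninformative names,
point-of-care variants sharing the original code), and stream mutations
(delete a concept's orders, thin its administrations by yearly factors,
delete one provenance stream). The default one-per-class slate targets
top-200 names whose codes are outside the concept library (lab renames
excepted — they keep their code), so harmonization injections do not leak
into the ratio series and precision can be scored cleanly.
`ledger_recall` then scores findings and flags against the ledger, per
class and overall.

## What the synthetic data does and does not show

The generator reproduces the *structural* properties the audits key on:
1:1 name/code mappings at several granularities, overlapping provenance
streams with known probabilities, stable-by-default ratio schedules, and
every error class with known ground truth. It deliberately does not model
visit structure, demographics, correlated comorbidity, code-frequency
distributions of any real institution, raw-name messiness beyond the
injected classes, or privacy properties. Passing tests therefore
demonstrate that the audit logic detects what it claims to detect under
known conditions — not that any particular real extract is clean, nor that
the severity taxonomy covers every failure mode of real source systems.

## Numerical choices and degenerate inputs

Integer percentages round half up. Medians use the standard even/odd
definition, so `.5` medians are possible and reported as such. Empty record
collections: top-N selection returns an empty result; cardinality raises
(there is nothing to summarize); a missing domain is reported as absent
without affecting the others; an empty ratio-plot request is a warned
no-op. Null/empty raw names are excluded from ranking but counted. The
problem sizes used by the test suite and the acceptance script (10 000
patients for the clean invariant, 5 000 for injection scoring, 4 000 for
parameter recovery, 30 for brute-force oracle equivalence) are the
package's chosen study conditions: large enough for the stated statistical
tolerances (±5 points on provenance percentages at ≥500 concept patients,
±10% relative on ratio schedules at ≥200 orders/year), small enough to run
comfortably on one CPU.

## Known limitations

No gold standard: the completeness audit flags inconsistencies between
streams but cannot say which stream is wrong. Overcounting (one order
yielding several administration records within a stream) is out of scope;
ratios are within-partner comparisons only. The severity cascade is
deliberately conservative and first-match-wins; a pair exhibiting several
issues reports only the first. Token-overlap fidelity can miss-grade names
whose spelling shares no tokens or prefixes with the reference
(trade names absent from the brand vocabulary grade as uninformative
rather than mismatched). Code matching is exact (an optional prefix mode
for hierarchical diagnosis codes is off by default).
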