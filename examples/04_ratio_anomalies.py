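"""Administration/order ratio anomalies for medication concepts.

Clinical workflows keep the ratio of administration records to order
records roughly stable over time, so a strong decline (here injected by
thinning administrations year over year) is flagged as drift, and a concept
whose orders were never loaded (deleted here) is flagged as extreme — both
patterns point to missing records rather than practice change.
"""

from cdmaudit import (
    GeneratorConfig,
    IssueClass,
    IssueSpec,
    generate_clean,
    inject_issues,
)
from cdmaudit.completeness import completeness_report
from cdmaudit.reporting import plot_ratio_series

dataset, terminology, library = generate_clean(GeneratorConfig(seed=11, n_patients=4000))
specs = [
    IssueSpec(
        IssueClass.DECAY_ADMIN_RATIO,
        "chronic_kidney_disease/iron",
        magnitude={2016: 1.0, 2017: 0.8, 2018: 0.6, 2019: 0.45, 2020: 0.35, 2021: 0.25},
    ),
    IssueSpec(
        IssueClass.DROP_ORDER_STREAM,
        "chronic_kidney_disease/erythropoiesis_stimulating_agent",
    ),
]
dataset, _ledger = inject_issues(dataset, terminology, specs, seed=11, library=library)

report = completeness_report(dataset, library)
for concept in ("iron", "erythropoiesis_stimulating_agent", "ace_inhibitor"):
    series = report.ratio_series[("chronic_kidney_disease", concept)]
    print(concept)
    for p in series:
        ratio = "undefined" if p.ratio_pct is None else f"{p.ratio_pct:6.1f}%"
        flags = ",".join(sorted(p.flags)) or "-"
        print(f"  {p.year}: admin={p.n_admin_records:>4} orders={p.n_order_records:>4} ratio={ratio} flags={flags}")

ckd_series = {k: v for k, v in report.ratio_series.items() if k[0] == "chronic_kidney_disease"}
out = plot_ratio_series(ckd_series, "ckd_ratios.png")
print("plot written to", out)
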