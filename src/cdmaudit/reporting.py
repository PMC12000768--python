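"""Rendering of audit outputs: cardinality tables in "median (min, max)"
form, per-condition completeness tables with provenance sub-rows, and
administration/order ratio plots (log-scaled automatically when a series
contains extreme percentages)."""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .completeness import CompletenessReport, RatioPoint, Stratifier
from .harmonization import Direction, HarmonizationReport, RecordDomain

__all__ = [
    "format_cardinality_cell",
    "parse_cardinality_cell",
    "render_cardinality_table",
    "render_completeness_table",
    "plot_ratio_series",
]

log = logging.getLogger(__name__)

_DIRECTION_LABELS = {
    Direction.CODES_PER_NAME: "Codes per raw name",
    Direction.NAMES_PER_CODE: "Raw names per code",
}
_DOMAIN_LABELS = {
    RecordDomain.ORDERS: "Medication orders",
    RecordDomain.ADMINISTRATIONS: "Medication administrations",
    RecordDomain.LABS: "Laboratory results",
}


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def format_cardinality_cell(median: float, minimum: int, maximum: int) -> str:
    """E.g. median 1, min 1, max 805 -> ``"1 (1, 805)"``."""
    return f"{_fmt_num(median)} ({minimum}, {maximum})"


_CELL_RE = re.compile(r"^\s*([0-9.]+)\s*\(\s*(\d+)\s*,\s*(\d+)\s*\)\s*$")


def parse_cardinality_cell(cell: str) -> tuple[float, int, int]:
    """Inverse of :func:`format_cardinality_cell` (round-trip check)."""
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"unparseable cardinality cell {cell!r}")
    return float(m.group(1)), int(m.group(2)), int(m.group(3))


def render_cardinality_table(report: HarmonizationReport) -> tuple[pd.DataFrame, str]:
    """One row per direction x domain with a "median (min, max)" cell."""
    rows = []
    for direction in Direction:
        for domain in RecordDomain:
            stats = report.cardinality.get((direction, domain))
            cell = (
                format_cardinality_cell(stats.median, stats.minimum, stats.maximum)
                if stats is not None
                else "—"
            )
            rows.append(
                {
                    "direction": _DIRECTION_LABELS[direction],
                    "domain": _DOMAIN_LABELS[domain],
                    "median (min, max)": cell,
                }
            )
    frame = pd.DataFrame(rows)
    return frame, frame.to_string(index=False)


def render_completeness_table(
    report: CompletenessReport, condition: str
) -> tuple[pd.DataFrame, str]:
    """Per-condition table: cohort header row, then per concept a total row
    and one sub-row per provenance stratum with N and integer percent."""
    if condition not in report.cohorts:
        raise KeyError(
            f"condition {condition!r} not in report; available: "
            f"{sorted(report.cohorts)}"
        )
    years = list(report.years)
    cohort = report.cohorts[condition]
    rows: list[dict[str, object]] = []
    header: dict[str, object] = {"row": "Number of unique patients", "stratum": ""}
    for y in years:
        header[f"N {y}"] = cohort.size(y)
        header[f"% {y}"] = ""
    rows.append(header)

    by_concept: dict[tuple[str, str], list] = {}
    for c in report.counts:
        if c.condition != condition:
            continue
        by_concept.setdefault((c.category.value, c.concept), []).append(c)
    for (_category, concept), counts in by_concept.items():
        totals = {c.year: c for c in counts if c.stratifier is Stratifier.NONE}
        row: dict[str, object] = {"row": concept, "stratum": ""}
        for y in years:
            row[f"N {y}"] = totals[y].concept_total if y in totals else ""
            row[f"% {y}"] = ""
        rows.append(row)
        strata = sorted(
            {
                c.stratum
                for c in counts
                if c.stratifier is Stratifier.PROVENANCE and c.n_patients > 0
            }
        )
        for stratum in strata:
            srow: dict[str, object] = {"row": f"  {concept}", "stratum": stratum}
            per_year = {
                c.year: c
                for c in counts
                if c.stratifier is Stratifier.PROVENANCE and c.stratum == stratum
            }
            for y in years:
                c = per_year.get(y)
                srow[f"N {y}"] = c.n_patients if c else ""
                srow[f"% {y}"] = (
                    f"{c.pct}%" if c is not None and c.pct is not None else ""
                )
            rows.append(srow)
    frame = pd.DataFrame(rows)
    return frame, frame.to_string(index=False)


def plot_ratio_series(
    series_by_concept: Mapping[tuple[str, str], Sequence[RatioPoint]],
    path: str | Path,
    log_threshold_pct: float = 1000.0,
):
    """Plot yearly administration/order percent ratios, one line per concept.

    Flagged points are marked; the y-axis switches to log scale when any
    ratio reaches ``log_threshold_pct``.  Empty input is a warned no-op.
    """
    if not series_by_concept:
        log.warning("no ratio series to plot; skipping %s", path)
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    max_ratio = 0.0
    for (condition, concept), series in series_by_concept.items():
        pts = sorted(series, key=lambda p: p.year)
        xs = [p.year for p in pts if p.ratio_pct is not None]
        ys = [p.ratio_pct for p in pts if p.ratio_pct is not None]
        if ys:
            max_ratio = max(max_ratio, max(ys))
        (line,) = ax.plot(xs, ys, marker="o", label=f"{condition}/{concept}")
        fx = [p.year for p in pts if p.flags and p.ratio_pct is not None]
        fy = [p.ratio_pct for p in pts if p.flags and p.ratio_pct is not None]
        if fx:
            ax.scatter(fx, fy, marker="x", s=90, color=line.get_color(), zorder=3)
    if max_ratio >= log_threshold_pct:
        ax.set_yscale("log")
    ax.axhline(100.0, linestyle="--", linewidth=0.8, color="grey")
    ax.set_xlabel("Year")
    ax.set_ylabel("Administrations / orders (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
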