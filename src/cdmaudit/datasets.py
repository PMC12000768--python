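"""Bundled worked-example data.

``ckd_provenance_worked_example.csv`` is a transcribed worked example of
provenance-stratified completeness counts for a chronic kidney disease
cohort: diagnosis concepts at one data partner and procedure concepts at
another, 2016-2021, with clinician-entered/ordered and billing strata.  Each
row carries the concept-year denominator (distinct patients with the
concept), the stratum numerator and the integer percentage printed in the
original rendering of the table.

Five cells in the original rendering are internally inconsistent: no single
deterministic rounding rule (half-up, half-even or truncation) reproduces
their printed percentage from the printed counts, while half-up reproduces
all 79 remaining cells.  They are listed in ``INCONSISTENT_CELLS`` and
excluded from exact-match checks (every one is off by a single point).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .completeness import round_half_up_percent

__all__ = [
    "load_provenance_worked_example",
    "INCONSISTENT_CELLS",
]

#: (section, concept, year, stratum) of printed percentages that disagree
#: with every deterministic rounding of the printed counts.
INCONSISTENT_CELLS: frozenset[tuple[str, str, int, str]] = frozenset(
    {
        ("diagnoses_dp1", "pericarditis", 2016, "billing"),  # 388/394 = 98.48, printed 99
        ("procedures_dp2", "dialysis", 2018, "ordered"),  # 1063/1257 = 84.57, printed 84
        ("procedures_dp2", "dialysis", 2017, "billing"),  # 1290/1295 = 99.61, printed 99
        ("procedures_dp2", "dialysis", 2018, "billing"),  # 1251/1257 = 99.52, printed 99
        ("procedures_dp2", "pyelography", 2021, "ordered"),  # 322/405 = 79.51, printed 79
    }
)


def load_provenance_worked_example() -> pd.DataFrame:
    """Worked-example counts with recomputed integer percentages.

    Returns the bundled table with two added columns: ``pct_computed``
    (round-half-up integer percent of ``n_patients / concept_total``) and
    ``consistent`` (whether the cell is outside ``INCONSISTENT_CELLS``).
    """
    with resources.files("cdmaudit.data").joinpath(
        "ckd_provenance_worked_example.csv"
    ).open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh)
    frame["pct_computed"] = [
        round_half_up_percent(int(n), int(d))
        for n, d in zip(frame["n_patients"], frame["concept_total"])
    ]
    frame["consistent"] = [
        (s, c, int(y), st) not in INCONSISTENT_CELLS
        for s, c, y, st in zip(
            frame["section"], frame["concept"], frame["year"], frame["stratum"]
        )
    ]
    return frame
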