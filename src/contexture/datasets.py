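"""Worked-example data: the published clinicopathological summary of the
75-patient early-stage oral tongue cancer cohort the pipeline was designed
around.

Only printed group-level counts are available (no per-cell or per-patient
data were deposited), so this module carries the counts of the two
score-defined groups (43 score-low, 32 score-high patients) together with
the percentages as printed, for arithmetic reconstruction and as README /
acceptance inputs.
"""

from __future__ import annotations

import pandas as pd

from .stats import round_half_away

__all__ = [
    "GROUP_SIZES",
    "oral_tongue_table_one",
    "recompute_percentages",
]

GROUP_SIZES: dict[str, int] = {"low": 43, "high": 32}

#: (variable, level, count_low, printed_pct_low, count_high, printed_pct_high)
_ROWS = [
    ("sex", "male", 26, 60, 16, 50),
    ("sex", "female", 17, 40, 16, 50),
    ("pT", "pT1", 19, 44, 19, 59),
    ("pT", "pT2", 20, 47, 10, 31),
    ("pT", "pT3", 4, 9, 3, 10),
    ("pN", "pN0", 39, 91, 30, 94),
    ("pN", "pN1", 4, 9, 2, 6),
    ("pStage", "1", 18, 42, 18, 56),
    ("pStage", "2", 17, 40, 9, 28),
    ("pStage", "3", 8, 18, 5, 16),
    ("grade", "well", 6, 14, 10, 31),
    ("grade", "moderate", 32, 74, 18, 56),
    ("grade", "poor", 5, 12, 4, 13),
    ("lvi", "absent", 39, 91, 29, 91),
    ("lvi", "present", 4, 9, 3, 9),
    ("survival_5y", "alive", 28, 65, 28, 88),
    ("survival_5y", "dead", 15, 35, 4, 12),
    ("recurrence", "none", 37, 86, 28, 88),
    ("recurrence", "recurrence", 6, 14, 4, 12),
]


def oral_tongue_table_one() -> pd.DataFrame:
    """Printed counts and percentages per score group, one row per level."""
    return pd.DataFrame(
        _ROWS,
        columns=["variable", "level", "count_low", "printed_pct_low",
                 "count_high", "printed_pct_high"],
    )


def recompute_percentages(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute group percentages from the printed counts.

    Adds ``pct_low`` / ``pct_high`` columns (100 * count / group size,
    rounded half away from zero) next to the printed values. A handful of
    printed cells were evidently hand-rounded (e.g. 12.5% appearing as both
    12% and 13% in different rows), so exact agreement over every cell is
    not attainable under any single deterministic rounding rule.
    """
    table = oral_tongue_table_one() if table is None else table.copy()
    table["pct_low"] = [round_half_away(100 * c / GROUP_SIZES["low"])
                        for c in table["count_low"]]
    table["pct_high"] = [round_half_away(100 * c / GROUP_SIZES["high"])
                         for c in table["count_high"]]
    return table
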