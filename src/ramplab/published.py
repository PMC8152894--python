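"""Printed summary data from the reference corticostriatal recording dataset.

The raw recordings behind the reference dataset are not archived, but its
printed summary tables are valid inputs: per-animal neuron counts for each
recording day (medial frontal cortex and dorsomedial striatum), and the
day-1 counts of interval-modulated neurons per area.  These feed the
count-arithmetic checks and the contingency analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2

#: Neurons recorded per animal (1-7) and day (0-3): {day: {"MFC": [...], "DMS": [...]}}
NEURON_COUNTS = {
    0: {"MFC": [7, 7, 15, 11, 3, 6, 10], "DMS": [9, 9, 14, 8, 4, 8, 15]},
    1: {"MFC": [5, 7, 8, 5, 3, 6, 13], "DMS": [5, 9, 9, 2, 5, 8, 20]},
    2: {"MFC": [7, 6, 7, 6, 4, 6, 11], "DMS": [4, 7, 8, 3, 3, 8, 21]},
    3: {"MFC": [10, 6, 11, 9, 4, 10, 14], "DMS": [6, 11, 13, 4, 8, 11, 27]},
}

#: Day-1 interval-modulation screen outcome: (modulated, total) per area.
DAY1_INTERVAL_MODULATED = {"MFC": (10, 47), "DMS": (28, 58)}


def neuron_count_table() -> pd.DataFrame:
    """Long table (day, animal, area, n_neurons) of recorded-unit counts."""
    rows = []
    for day, areas in NEURON_COUNTS.items():
        for area, counts in areas.items():
            for animal, n in enumerate(counts, start=1):
                rows.append({"day": day, "animal": animal, "area": area, "n_neurons": n})
    return pd.DataFrame(rows)


def count_totals() -> dict:
    """Summed neuron counts: per-area two-interval totals and the grand total.

    Two-interval sessions are Days 1-3; Day 0 is the one-interval session.
    """
    df = neuron_count_table()
    two = df[df["day"] > 0]
    return {
        "mfc_two_interval": int(two.loc[two["area"] == "MFC", "n_neurons"].sum()),
        "dms_two_interval": int(two.loc[two["area"] == "DMS", "n_neurons"].sum()),
        "two_interval_total": int(two["n_neurons"].sum()),
        "grand_total": int(df["n_neurons"].sum()),
    }


def day1_modulation_table() -> ContingencyTable2x2:
    """2x2 table of day-1 interval-modulated vs not, by area."""
    counts = np.array(
        [
            [m, n - m]
            for m, n in (DAY1_INTERVAL_MODULATED["MFC"], DAY1_INTERVAL_MODULATED["DMS"])
        ]
    )
    return ContingencyTable2x2(counts=counts)
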