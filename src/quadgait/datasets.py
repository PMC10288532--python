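"""Published reference values bundled for regression checks and examples.

Group-level tables from an eight-cat staggered-thoracic-hemisection
treadmill study (tied-belt locomotion at 0.4 m/s): per-cat 2:1 fore-hind
coordination counts at four post-lesion time points, and per-cat mean
resultant lengths (r) of right homolateral phase intervals split by
coordination type. These printed values serve as inputs to the aggregation
operations; nothing in this module is computed.
"""

from __future__ import annotations

import pandas as pd

CATS = ("TO", "JA", "AR", "HO", "MB", "GR", "KA", "PO")

#: Post-lesion states in chronological order (intact first where present).
LESION_STATES = ("hemi1_wk1-2", "hemi1_wk7-8", "hemi2_wk1-4", "hemi2_wk7-8")

# (cycles with 2:1 coordination, total hindlimb cycles) per cat and state,
# with the percentage as printed (integer, rounded half-up).
_COORDINATION_COUNTS = {
    "TO": ((14, 14, 100), (16, 16, 100), (8, 13, 62), (12, 12, 100)),
    "JA": ((7, 12, 58), (11, 19, 58), (8, 8, 100), (22, 23, 96)),
    "AR": ((4, 8, 50), (21, 21, 100), (18, 24, 75), (23, 24, 96)),
    "HO": ((6, 24, 25), (2, 10, 20), (12, 17, 71), (15, 21, 71)),
    "MB": ((22, 22, 100), (28, 34, 82), (4, 14, 29), (2, 19, 11)),
    "GR": ((1, 10, 10), (7, 36, 19), (11, 21, 52), (6, 12, 50)),
    "KA": ((4, 26, 15), (2, 23, 9), (21, 21, 100), (12, 17, 71)),
    "PO": ((6, 18, 33), (1, 8, 13), (17, 19, 89), (7, 8, 88)),
}

# Per-cat mean resultant length r of right homolateral phase intervals,
# split by coordination type (None where the cat did not display the type).
# Row order per cat: intact, then the four post-lesion states.
_R_TABLE = {
    "TO": ((0.79, None, None), (None, 0.74, 0.68), (None, 0.75, 0.44),
           (0.91, 0.42, 0.60), (None, 0.70, 0.64)),
    "JA": ((0.86, None, None), (0.45, 0.64, 0.27), (0.74, 0.30, 0.35),
           (None, 0.83, 0.86), (None, 0.58, 0.33)),
    "AR": ((0.88, None, None), (0.94, 0.85, 0.49), (None, 0.84, 0.80),
           (0.80, 0.47, 0.54), (None, 0.51, 0.57)),
    "HO": ((0.97, None, None), (0.57, 0.23, 0.48), (0.69, None, None),
           (0.44, 0.46, 0.48), (0.87, 0.42, 0.42)),
    "MB": ((0.96, None, None), (None, 0.23, 0.54), (0.52, 0.33, 0.50),
           (0.71, 0.39, 0.49), (0.60, 0.48, 0.10)),
    "GR": ((1.00, None, None), (0.92, None, None), (0.75, 0.37, 0.17),
           (0.38, 0.61, 0.12), (0.44, 0.41, 0.39)),
    "KA": ((0.97, None, None), (0.93, 0.12, 0.64), (0.85, 0.42, 0.12),
           (None, 0.46, 0.38), (0.97, 0.48, 0.57)),
    "PO": ((0.90, None, None), (0.88, 0.55, 0.70), (0.13, None, None),
           (0.46, 0.46, 0.47), (None, 0.35, 0.43)),
}

#: Percentage of cycles with 1:2 fore-hind coordination during quadrupedal
#: locomotion after complete spinal transection (three cats).
SPINAL_1TO2_PERCENT = {"TO": 21, "JA": 20, "HO": 48}


def coordination_counts() -> pd.DataFrame:
    """Per-cat 2:1 coordination counts: columns ``subject, state,
    n_2to1, n_total, printed_percent``."""
    rows = []
    for cat in CATS:
        for state, (k, n, pct) in zip(LESION_STATES, _COORDINATION_COUNTS[cat]):
            rows.append((cat, state, k, n, pct))
    return pd.DataFrame(rows, columns=["subject", "state", "n_2to1",
                                       "n_total", "printed_percent"])


def r_table() -> pd.DataFrame:
    """Per-cat mean resultant lengths, tidy: ``subject, state, label, r``.

    Labels are ``1:1``, ``2:1-first`` and ``2:1-second``; rows with no
    value (the cat did not display the type) carry r = NaN.
    """
    states = ("intact",) + LESION_STATES
    labels = ("1:1", "2:1-first", "2:1-second")
    rows = []
    for cat in CATS:
        for state, cells in zip(states, _R_TABLE[cat]):
            for label, r in zip(labels, cells):
                rows.append((cat, state, label,
                             float(r) if r is not None else float("nan")))
    return pd.DataFrame(rows, columns=["subject", "state", "label", "r"])
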