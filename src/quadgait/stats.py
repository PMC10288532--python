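"""Asymmetry indexes, group aggregation and the nonparametric test battery.

Left-right asymmetry is right-limb mean minus left-limb mean (a value that
negates under L/R relabelling). State effects on repeated-measures
variables use the one-factor Friedman test with post hoc pairwise Wilcoxon
signed-rank tests under Bonferroni correction; per-state normality is
screened with Shapiro-Wilk. Mean resultant lengths (r) are aggregated
across subjects per state x coordination label as min, max, mean and
sample SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class AsymmetryIndex:
    """Right-limb mean minus left-limb mean, same units as the variable."""

    variable: str
    value: float
    subject: str = ""
    state: str = ""


def asymmetry_index(right_values, left_values, variable: str,
                    subject: str = "", state: str = "") -> AsymmetryIndex:
    """mean(right) - mean(left); NaN when either side is missing/empty."""
    r = np.asarray(right_values, dtype=float).ravel()
    l = np.asarray(left_values, dtype=float).ravel()
    if r.size == 0 or l.size == 0:
        logger.warning("missing side for %s (%s/%s); index undefined",
                       variable, subject, state)
        value = np.nan
    else:
        value = float(r.mean() - l.mean())
    return AsymmetryIndex(variable=variable, value=value,
                          subject=subject, state=state)


def asymmetry_table(temporal_summary: pd.DataFrame,
                    pairs=(("RF", "LF"), ("RH", "LH")),
                    variables=("cycle_mean", "stance_mean", "swing_mean")
                    ) -> pd.DataFrame:
    """Per subject x state asymmetry indexes from a temporal summary table."""
    rows = []
    for (subject, state), sub in temporal_summary.groupby(["subject", "state"]):
        by_limb = sub.set_index("limb")
        for right, left in pairs:
            if right not in by_limb.index or left not in by_limb.index:
                continue
            for var in variables:
                rows.append((subject, state, f"{right}-{left}", var,
                             float(by_limb.loc[right, var]
                                   - by_limb.loc[left, var])))
    return pd.DataFrame(rows, columns=["subject", "state", "pair",
                                       "variable", "value"])


@dataclass
class PairwiseTest:
    pair: tuple[str, str]
    statistic: float
    p: float
    significant: bool


@dataclass
class StateComparisonResult:
    """Friedman main effect plus Bonferroni-corrected pairwise Wilcoxon tests.

    ``alpha_adjusted = 0.05 / m`` with m the number of pairwise comparisons
    emitted. ``underpowered`` is set (and no p-values emitted) with fewer
    than 3 complete subjects.
    """

    variable: str
    n_subjects: int
    friedman_statistic: float | None = None
    friedman_p: float | None = None
    shapiro_p: dict[str, float] = field(default_factory=dict)
    pairwise: list[PairwiseTest] = field(default_factory=list)
    n_comparisons: int = 0
    alpha_adjusted: float | None = None
    underpowered: bool = False


def compare_states(values: pd.DataFrame, variable: str = "",
                   alpha: float = ALPHA) -> StateComparisonResult:
    """Repeated-measures comparison of a variable across states.

    ``values`` is wide: one row per subject, one column per state (at
    least 3). Subjects missing any state are dropped listwise. When the
    Friedman test rejects at ``alpha``, all pairwise Wilcoxon signed-rank
    tests are run (exact small-sample distribution where possible) and
    flagged significant at the Bonferroni-adjusted level ``alpha / m``.
    """
    if values.shape[1] < 3:
        raise ValueError("need at least 3 states for a Friedman comparison")
    complete = values.dropna(axis=0, how="any")
    result = StateComparisonResult(variable=variable, n_subjects=len(complete))
    if len(complete) < 3:
        logger.warning("%s: only %d complete subjects; underpowered, "
                       "no p-values emitted", variable, len(complete))
        result.underpowered = True
        return result

    for state in complete.columns:
        x = complete[state].to_numpy(dtype=float)
        # Shapiro-Wilk requires dispersion; constant samples are reported NaN
        result.shapiro_p[state] = (float(sps.shapiro(x).pvalue)
                                   if np.ptp(x) > 0 else np.nan)

    rows = complete.to_numpy(dtype=float)
    if np.all(np.ptp(rows, axis=1) == 0):
        # every subject identical across states: no evidence of an effect
        # (the tie correction is undefined there)
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*rows.T)
    result.friedman_statistic, result.friedman_p = float(stat), float(p)

    if p < alpha:
        pairs = list(combinations(complete.columns, 2))
        m = len(pairs)
        result.n_comparisons = m
        result.alpha_adjusted = alpha / m
        for a, b in pairs:
            x = complete[a].to_numpy(dtype=float)
            y = complete[b].to_numpy(dtype=float)
            method = "exact" if len(x) <= 25 else "approx"
            try:
                w = sps.wilcoxon(x, y, method=method)
            except ValueError:
                w = sps.wilcoxon(x, y, method="approx")
            result.pairwise.append(PairwiseTest(
                pair=(a, b), statistic=float(w.statistic),
                p=float(w.pvalue), significant=w.pvalue < alpha / m))
    return result


def summarize_r_table(r_values: pd.DataFrame,
                      group_keys=("state", "label")) -> pd.DataFrame:
    """min/max/mean/sample-SD of mean resultant lengths across subjects.

    ``r_values`` is tidy with columns ``subject``, the ``group_keys`` and
    ``r``. Subjects lacking a coordination type in a state simply have no
    row and are excluded. A single-subject group reports SD as NaN with
    ``n = 1``; empty groups produce no row.
    """
    sub = r_values.dropna(subset=["r"])
    if sub.empty:
        return pd.DataFrame(columns=[*group_keys, "n", "r_min", "r_max",
                                     "r_mean", "r_sd"])
    g = sub.groupby(list(group_keys), sort=True)["r"]
    out = g.agg(n="size", r_min="min", r_max="max", r_mean="mean",
                r_sd=lambda x: x.std(ddof=1)).reset_index()
    out["n"] = out["n"].astype(int)
    return out
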