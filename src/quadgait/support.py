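"""Support-period decomposition over normalized right-hindlimb cycles.

Between any two consecutive gait events the set of limbs in stance is
constant; sweeping the merged event sequence yields a piecewise-constant
support timeline. Within a reference right-hindlimb cycle, time in each of
the nine canonical quadrupedal support configurations (four triple-support,
two diagonal, two homolateral double-support, quadrupedal) is expressed as
a percentage of cycle duration. Configurations outside the nine (aerial,
single-limb, girdle-only doubles) are reported under ``other``, never
folded into neighbours, so the ten buckets always sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import CONTACT, LIMBS, GaitEventTable, LimbCycle

#: Canonical support configurations, keyed by the stance set.
CATEGORY_BY_CONFIG = {
    frozenset({"LH", "RH", "RF"}): "triple_LH_RH_RF",
    frozenset({"LF", "RH"}): "diag_LF_RH",
    frozenset({"LF", "RF", "RH"}): "triple_LF_RF_RH",
    frozenset({"RF", "RH"}): "homolateral_RF_RH",
    frozenset({"LH", "RH", "LF"}): "triple_LH_RH_LF",
    frozenset({"RF", "LH"}): "diag_RF_LH",
    frozenset({"LF", "RF", "LH"}): "triple_LF_RF_LH",
    frozenset({"LF", "LH"}): "homolateral_LF_LH",
    frozenset(LIMBS): "quad",
}
CATEGORIES = tuple(CATEGORY_BY_CONFIG.values()) + ("other",)

#: Left-right mirror pairs among the canonical categories.
MIRROR = {
    "triple_LH_RH_RF": "triple_LH_RH_LF",
    "triple_LH_RH_LF": "triple_LH_RH_RF",
    "diag_LF_RH": "diag_RF_LH",
    "diag_RF_LH": "diag_LF_RH",
    "triple_LF_RF_RH": "triple_LF_RF_LH",
    "triple_LF_RF_LH": "triple_LF_RF_RH",
    "homolateral_RF_RH": "homolateral_LF_LH",
    "homolateral_LF_LH": "homolateral_RF_RH",
    "quad": "quad",
    "other": "other",
}


@dataclass(frozen=True)
class SupportSegment:
    """Maximal interval with a constant stance configuration.

    ``known`` is False while any limb's state is still undetermined
    (before that limb's first event).
    """

    start: float
    end: float
    limbs: frozenset
    known: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


def support_configuration_timeline(table: GaitEventTable) -> list[SupportSegment]:
    """Sweep merged events into a piecewise-constant support timeline.

    Each limb toggles into stance at contact and out at liftoff. Before a
    limb's first event its state is unknown and the segment is flagged.
    Zero-length segments (simultaneous events) are dropped.
    """
    ev = table.events.sort_values("time_s", kind="stable")
    times = ev["time_s"].to_numpy(dtype=float)
    limbs = ev["limb"].to_list()
    kinds = ev["event"].to_list()

    state: dict[str, bool | None] = {limb: None for limb in LIMBS}
    segments: list[SupportSegment] = []
    boundaries = np.unique(times)
    if len(boundaries) == 0:
        return segments
    k = 0
    # the configuration after the last event persists (open-ended segment)
    for b, nxt in zip(boundaries, np.append(boundaries[1:], np.inf)):
        while k < len(times) and times[k] <= b:
            state[limbs[k]] = kinds[k] == CONTACT
            k += 1
        in_stance = frozenset(l for l, s in state.items() if s)
        known = all(s is not None for s in state.values())
        segments.append(SupportSegment(float(b), float(nxt), in_stance, known))
    return segments


@dataclass
class SupportDecomposition:
    """Per-cycle support durations and percentages by category.

    ``partial`` is True when the timeline does not fully cover the cycle
    window with known limb states; percentages of complete decompositions
    sum to exactly 100.
    """

    cycle_idx: int
    cycle_duration: float
    durations: dict[str, float]
    percents: dict[str, float]
    partial: bool


def decompose_cycle(timeline: list[SupportSegment],
                    rh_cycle: LimbCycle) -> SupportDecomposition:
    """Intersect the support timeline with one reference hindlimb cycle.

    Segments straddling the cycle boundary are clipped to the half-open
    window ``[contact_start, contact_end)``. Recurrences of the same
    configuration within a cycle are summed: the categories are identified
    by stance set, not order of occurrence.
    """
    t0, t1 = rh_cycle.contact_start, rh_cycle.contact_end
    durations = {cat: 0.0 for cat in CATEGORIES}
    covered = 0.0
    partial = False
    for seg in timeline:
        lo, hi = max(seg.start, t0), min(seg.end, t1)
        if hi <= lo:
            continue
        if not seg.known:
            partial = True
            continue
        cat = CATEGORY_BY_CONFIG.get(seg.limbs, "other")
        durations[cat] += hi - lo
        covered += hi - lo
    if covered < rh_cycle.cycle_duration - 1e-9:
        partial = True
    denom = rh_cycle.cycle_duration
    percents = {cat: 100.0 * d / denom for cat, d in durations.items()}
    return SupportDecomposition(
        cycle_idx=rh_cycle.index, cycle_duration=denom,
        durations=durations, percents=percents, partial=partial)


def decompose_trial(table: GaitEventTable,
                    rh_cycles: list[LimbCycle]) -> list[SupportDecomposition]:
    """Decompose every reference hindlimb cycle of a trial."""
    timeline = support_configuration_timeline(table)
    return [decompose_cycle(timeline, c) for c in rh_cycles]


def decompositions_to_frame(decomps: list[SupportDecomposition],
                            meta=None) -> pd.DataFrame:
    """Tidy long frame ``subject,state,cycle_idx,category,duration_s,percent``.

    Partial decompositions are excluded (their percentages are not
    comparable across cycles).
    """
    rows = []
    subject = getattr(meta, "subject", "")
    state = getattr(meta, "state", "")
    for d in decomps:
        if d.partial:
            continue
        for cat in CATEGORIES:
            rows.append((subject, state, d.cycle_idx, cat,
                         d.durations[cat], d.percents[cat]))
    return pd.DataFrame(rows, columns=["subject", "state", "cycle_idx",
                                       "category", "duration_s", "percent"])


def aggregate_support(frame: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean and SD percent per category.

    Percentages are averaged within subject first, then across subjects
    per state, mirroring per-animal means entering group bars.
    """
    if frame.empty:
        return pd.DataFrame(columns=["state", "category", "mean_percent",
                                     "sd_percent", "n_subjects"])
    per_subject = (frame.groupby(["state", "subject", "category"], sort=True)
                   ["percent"].mean().reset_index())
    g = per_subject.groupby(["state", "category"], sort=True)["percent"]
    out = g.agg(mean_percent="mean", sd_percent="std",
                n_subjects="size").reset_index()
    out.loc[out["n_subjects"] == 1, "sd_percent"] = 0.0
    return out
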