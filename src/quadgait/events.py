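"""Gait-event tables, validation, cycle segmentation and temporal variables.

A trial is described by per-limb sequences of paw-contact and liftoff times
(seconds). Contact is the first instant of ground contact; liftoff the end of
stance (most caudal toe excursion). Cycles run from one contact of a limb to
its next contact; stance is contact-to-liftoff and swing the remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIMBS = ("LF", "RF", "LH", "RH")
FORELIMBS = ("LF", "RF")
HINDLIMBS = ("LH", "RH")

#: Locomotor-state labels: intact, weeks 1-2 / 7-8 after a first thoracic
#: hemisection, weeks 1-4 / 7-8 after a second (staggered) hemisection, and
#: after complete spinal transection.
STATES = (
    "intact",
    "hemi1_wk1-2",
    "hemi1_wk7-8",
    "hemi2_wk1-4",
    "hemi2_wk7-8",
    "spinal",
)

CONTACT = "contact"
LIFTOFF = "liftoff"


class GaitValidationError(ValueError):
    """Raised when an event table violates its structural invariants.

    Attributes
    ----------
    violations : list of dict
        One record per problem with keys ``limb``, ``row`` (0-based row in
        the source table, or None) and ``message``.
    """

    def __init__(self, violations: list[dict]):
        self.violations = violations
        lines = "; ".join(
            f"{v['limb'] or '?'} row {v['row']}: {v['message']}" for v in violations
        )
        super().__init__(f"invalid gait event table: {lines}")


@dataclass(frozen=True)
class TrialMeta:
    """Trial metadata: treadmill belt speed, camera frame rate and labels."""

    belt_speed: float
    frame_rate: float
    subject: str = "synthetic"
    state: str = "intact"

    def __post_init__(self):
        if self.belt_speed <= 0:
            raise ValueError(f"belt_speed must be > 0, got {self.belt_speed}")
        if self.frame_rate < 0:
            raise ValueError(f"frame_rate must be >= 0, got {self.frame_rate}")
        if self.state not in STATES:
            raise ValueError(
                f"unknown state label {self.state!r}; expected one of {STATES}"
            )


@dataclass
class GaitEventTable:
    """Validated per-limb alternating contact/liftoff timestamps.

    ``events`` is a long DataFrame with columns ``limb``, ``event``
    (``contact``/``liftoff``) and ``time_s``, sorted by limb then time.
    Per limb, events strictly increase in time and strictly alternate
    starting with a contact.
    """

    events: pd.DataFrame
    meta: TrialMeta

    def __post_init__(self):
        violations = validate_events(self.events)
        if violations:
            raise GaitValidationError(violations)
        self.events = (
            self.events.sort_values(["limb", "time_s"], kind="stable")
            .reset_index(drop=True)
        )

    def limb_times(self, limb: str, event: str) -> np.ndarray:
        sel = (self.events["limb"] == limb) & (self.events["event"] == event)
        return self.events.loc[sel, "time_s"].to_numpy(dtype=float)

    def contacts(self, limb: str) -> np.ndarray:
        return self.limb_times(limb, CONTACT)

    def liftoffs(self, limb: str) -> np.ndarray:
        return self.limb_times(limb, LIFTOFF)

    @property
    def span(self) -> tuple[float, float]:
        t = self.events["time_s"]
        return float(t.min()), float(t.max())

    def shifted(self, dt: float) -> "GaitEventTable":
        """Return a copy with all event times shifted by ``dt`` seconds."""
        ev = self.events.copy()
        ev["time_s"] = ev["time_s"] + dt
        return GaitEventTable(ev, self.meta)

    def relabeled_lr(self) -> "GaitEventTable":
        """Return a copy with left and right limb labels swapped."""
        swap = {"LF": "RF", "RF": "LF", "LH": "RH", "RH": "LH"}
        ev = self.events.copy()
        ev["limb"] = ev["limb"].map(swap)
        return GaitEventTable(ev, self.meta)

    def to_csv(self, path) -> None:
        """Write the ``limb,event,time_s`` CSV dialect."""
        out = self.events.copy()
        out["time_s"] = out["time_s"].map(lambda t: format(t, ".9f"))
        out.to_csv(path, index=False)


def validate_events(events: pd.DataFrame) -> list[dict]:
    """Check the structural invariants of a long event table.

    Returns a list of violation records (see :class:`GaitValidationError`);
    an empty list means the table is valid.
    """
    problems: list[dict] = []
    required = {"limb", "event", "time_s"}
    missing = required - set(events.columns)
    if missing:
        return [{"limb": None, "row": None,
                 "message": f"missing columns {sorted(missing)}"}]

    for row, rec in enumerate(events.itertuples(index=False)):
        if rec.limb not in LIMBS:
            problems.append({"limb": rec.limb, "row": row,
                             "message": f"unknown limb label {rec.limb!r}"})
        if rec.event not in (CONTACT, LIFTOFF):
            problems.append({"limb": rec.limb, "row": row,
                             "message": f"unknown event kind {rec.event!r}"})
        if not np.isfinite(rec.time_s) or rec.time_s < 0:
            problems.append({"limb": rec.limb, "row": row,
                             "message": f"invalid time {rec.time_s}"})
    if problems:
        return problems

    for limb in LIMBS:
        sub = events[events["limb"] == limb].sort_values("time_s", kind="stable")
        rows = sub.index.to_list()
        kinds = sub["event"].to_list()
        times = sub["time_s"].to_numpy(dtype=float)
        if len(sub) == 0:
            continue
        if kinds[0] != CONTACT:
            problems.append({"limb": limb, "row": rows[0],
                             "message": "first event must be a contact"})
        for i in range(1, len(kinds)):
            if times[i] <= times[i - 1]:
                problems.append({"limb": limb, "row": rows[i],
                                 "message": "event times must strictly increase"})
            if kinds[i] == kinds[i - 1]:
                problems.append({"limb": limb, "row": rows[i],
                                 "message": f"two consecutive {kinds[i]} events"})
    return problems


def read_event_table(path, meta: TrialMeta) -> GaitEventTable:
    """Read and validate a ``limb,event,time_s`` CSV.

    Raises :class:`GaitValidationError` with row-level diagnostics if the
    file violates alternation, ordering or labelling invariants.
    """
    df = pd.read_csv(path)
    return GaitEventTable(df, meta)


def from_times(contacts: dict[str, np.ndarray],
               liftoffs: dict[str, np.ndarray],
               meta: TrialMeta) -> GaitEventTable:
    """Build a table from per-limb contact and liftoff time arrays."""
    frames = []
    for limb in LIMBS:
        for kind, times in ((CONTACT, contacts.get(limb, ())),
                            (LIFTOFF, liftoffs.get(limb, ()))):
            for t in np.asarray(times, dtype=float).ravel():
                frames.append((limb, kind, float(t)))
    df = pd.DataFrame(frames, columns=["limb", "event", "time_s"])
    df = df.sort_values(["limb", "time_s"], kind="stable").reset_index(drop=True)
    return GaitEventTable(df, meta)


@dataclass(frozen=True)
class LimbCycle:
    """One contact-to-contact cycle of a single limb.

    ``cycle_duration = contact_end - contact_start``;
    ``stance_duration = liftoff - contact_start``;
    ``swing_duration = cycle_duration - stance_duration``. The window is
    half-open: an event at exactly ``contact_end`` belongs to the next cycle.
    """

    limb: str
    index: int
    contact_start: float
    liftoff: float
    contact_end: float

    @property
    def cycle_duration(self) -> float:
        return self.contact_end - self.contact_start

    @property
    def stance_duration(self) -> float:
        return self.liftoff - self.contact_start

    @property
    def swing_duration(self) -> float:
        return self.cycle_duration - self.stance_duration

    @property
    def duty_factor(self) -> float:
        return self.stance_duration / self.cycle_duration


def segment_cycles(table: GaitEventTable, limb: str) -> list[LimbCycle]:
    """Segment one limb's events into contact-to-contact cycles.

    The trailing contact with no successor is dropped. Each cycle must
    contain exactly one liftoff in ``[contact_start, contact_end)``;
    cycles violating this are excluded with a logged warning.
    """
    contacts = table.contacts(limb)
    liftoffs = table.liftoffs(limb)
    cycles: list[LimbCycle] = []
    for i in range(len(contacts) - 1):
        c0, c1 = contacts[i], contacts[i + 1]
        inside = liftoffs[(liftoffs >= c0) & (liftoffs < c1)]
        if len(inside) != 1:
            logger.warning(
                "%s cycle %d [%g, %g): %d liftoffs found, expected 1; excluded",
                limb, i, c0, c1, len(inside))
            continue
        cycles.append(LimbCycle(limb, i, float(c0), float(inside[0]), float(c1)))
    return cycles


def segment_all(table: GaitEventTable) -> dict[str, list[LimbCycle]]:
    return {limb: segment_cycles(table, limb) for limb in LIMBS}


def temporal_variables(cycles_by_limb: dict[str, list[LimbCycle]],
                       meta: TrialMeta) -> pd.DataFrame:
    """Tidy long table of cycle/stance/swing durations per limb cycle.

    Columns: ``subject, state, limb, cycle_idx, cycle_s, stance_s, swing_s``.
    An empty cycle list yields an empty table.
    """
    rows = []
    for limb, cycles in cycles_by_limb.items():
        for c in cycles:
            rows.append((meta.subject, meta.state, limb, c.index,
                         c.cycle_duration, c.stance_duration, c.swing_duration))
    return pd.DataFrame(
        rows,
        columns=["subject", "state", "limb", "cycle_idx",
                 "cycle_s", "stance_s", "swing_s"],
    )


def temporal_summary(tidy: pd.DataFrame) -> pd.DataFrame:
    """Per subject x state x limb means and SDs of the temporal variables.

    Cycles are averaged within subject first; group-level aggregation
    across subjects is the caller's next step (see ``group_stats``).
    """
    if tidy.empty:
        return pd.DataFrame(
            columns=["subject", "state", "limb",
                     "cycle_mean", "cycle_sd", "stance_mean", "stance_sd",
                     "swing_mean", "swing_sd", "n_cycles"])
    g = tidy.groupby(["subject", "state", "limb"], sort=True)
    out = g.agg(
        cycle_mean=("cycle_s", "mean"), cycle_sd=("cycle_s", "std"),
        stance_mean=("stance_s", "mean"), stance_sd=("stance_s", "std"),
        swing_mean=("swing_s", "mean"), swing_sd=("swing_s", "std"),
        n_cycles=("cycle_s", "size"),
    ).reset_index()
    # a single cycle has no dispersion, not a missing one
    for col in ("cycle_sd", "stance_sd", "swing_sd"):
        out.loc[out["n_cycles"] == 1, col] = 0.0
    return out
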