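"""Spatial kinematics from horizontal marker trajectories.

All positions live on a body-fixed fore-aft axis, positive rostral, in
meters. A MarkerTable is a wide DataFrame with a uniform ``time_s`` grid
and one ``<marker>_x`` column per marker (``toe_LF_x`` ... ``shoulder_x``,
``hip_x``). Positions at event times are looked up by linear interpolation
between the two bracketing frames, since events are frame-quantized in
real recordings.

Measures:

* stride length: |toe displacement from contact to liftoff| plus the belt
  travel during swing (swing duration x belt speed);
* relative distance at contact/liftoff: signed toe minus girdle position
  (shoulder for forelimbs, hip for hindlimbs);
* homolateral interference: |fore toe - hind toe| on the same side at a
  limb's contact and liftoff.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .events import FORELIMBS, LimbCycle

logger = logging.getLogger(__name__)

#: Girdle marker referenced by each limb's relative-distance measure.
GIRDLE_OF = {"LF": "shoulder_x", "RF": "shoulder_x",
             "LH": "hip_x", "RH": "hip_x"}


def marker_position(markers: pd.DataFrame, column: str, times) -> np.ndarray:
    """Linearly interpolated marker position at the given times.

    Raises ValueError when a time falls outside the sampled span by more
    than one frame.
    """
    t = markers["time_s"].to_numpy(dtype=float)
    x = markers[column].to_numpy(dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    if np.any(times < t[0] - dt) or np.any(times > t[-1] + dt):
        raise ValueError(
            f"event time outside trajectory span [{t[0]}, {t[-1]}] "
            f"(+/- one frame) for {column}")
    return np.interp(times, t, x)


def stride_length(cycle: LimbCycle, markers: pd.DataFrame,
                  belt_speed: float, toe_column: str | None = None) -> float:
    """Stride length of one limb cycle.

    Distance covered by the toe between contact and liftoff plus the belt
    travel during swing (swing duration x belt speed).
    """
    col = toe_column or f"toe_{cycle.limb}_x"
    x_c, x_l = marker_position(markers, col,
                               [cycle.contact_start, cycle.liftoff])
    return float(abs(x_c - x_l) + cycle.swing_duration * belt_speed)


def stride_lengths(cycles: list[LimbCycle], markers: pd.DataFrame,
                   belt_speed: float) -> pd.DataFrame:
    rows = [(c.limb, c.index, stride_length(c, markers, belt_speed))
            for c in cycles]
    return pd.DataFrame(rows, columns=["limb", "cycle_idx", "stride_length_m"])


def relative_distance_at_events(cycles: list[LimbCycle],
                                markers: pd.DataFrame) -> pd.DataFrame:
    """Signed toe-minus-girdle distance at contact and liftoff per cycle.

    Positive values are rostral of the girdle. Forelimbs reference the
    shoulder marker, hindlimbs the hip marker. Events falling outside the
    trajectory yield missing values (logged), not an error.
    """
    rows = []
    for c in cycles:
        toe = f"toe_{c.limb}_x"
        girdle = GIRDLE_OF[c.limb]
        try:
            tx = marker_position(markers, toe, [c.contact_start, c.liftoff])
            gx = marker_position(markers, girdle, [c.contact_start, c.liftoff])
            d_contact, d_liftoff = (tx - gx).tolist()
        except ValueError as err:
            logger.warning("%s cycle %d: %s", c.limb, c.index, err)
            d_contact = d_liftoff = np.nan
        rows.append((c.limb, c.index, d_contact, d_liftoff))
    return pd.DataFrame(rows, columns=["limb", "cycle_idx",
                                       "dist_at_contact_m", "dist_at_liftoff_m"])


def homolateral_interference(cycles: list[LimbCycle],
                             markers: pd.DataFrame) -> pd.DataFrame:
    """|fore toe - hind toe| on the same side at each limb's contact/liftoff.

    Computed at the events of every limb; report templates typically keep
    the forelimb rows (left pair at LF events, right pair at RF events).
    """
    rows = []
    for c in cycles:
        side = c.limb[0]  # 'L' or 'R'
        fore, hind = f"toe_{side}F_x", f"toe_{side}H_x"
        try:
            fx = marker_position(markers, fore, [c.contact_start, c.liftoff])
            hx = marker_position(markers, hind, [c.contact_start, c.liftoff])
        except ValueError as err:
            logger.warning("%s cycle %d: %s", c.limb, c.index, err)
            continue
        for event, f_, h_, t in (("contact", fx[0], hx[0], c.contact_start),
                                 ("liftoff", fx[1], hx[1], c.liftoff)):
            rows.append((c.limb, c.index, event, t, float(abs(f_ - h_))))
    return pd.DataFrame(rows, columns=["limb", "cycle_idx", "event",
                                       "time_s", "distance_m"])


def spatial_summary(cycles_by_limb: dict[str, list[LimbCycle]],
                    markers: pd.DataFrame, belt_speed: float) -> pd.DataFrame:
    """Per-cycle stride length and relative distances for all limbs."""
    frames = []
    for limb, cycles in cycles_by_limb.items():
        if not cycles:
            continue
        sl = stride_lengths(cycles, markers, belt_speed)
        rd = relative_distance_at_events(cycles, markers)
        frames.append(sl.merge(rd, on=["limb", "cycle_idx"]))
    if not frames:
        return pd.DataFrame(columns=["limb", "cycle_idx", "stride_length_m",
                                     "dist_at_contact_m", "dist_at_liftoff_m"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Marker CSV dialects

def read_marker_table(path, dialect: str = "wide",
                      px_to_m: float | None = None) -> pd.DataFrame:
    """Read a marker trajectory CSV.

    ``wide``: header ``time_s,<marker>_x``. ``dlc``: DeepLabCut-style
    3-row header (scorer / bodyparts / coords) with a frame-index first
    column; requires ``px_to_m`` (meters per pixel) and a frame rate is
    recovered from a ``time_s`` bodypart if present, otherwise the index
    is kept as ``frame``.
    """
    if dialect == "wide":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("wide marker CSV must have a time_s column")
        return df
    if dialect != "dlc":
        raise ValueError(f"unknown marker dialect {dialect!r}")
    if px_to_m is None:
        raise ValueError("DeepLabCut dialect requires px_to_m (m per pixel); "
                         "calibration has no default")
    raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    out = {}
    for scorer, bodypart, coord in raw.columns:
        if coord != "x":
            continue
        out[f"{bodypart}_x"] = raw[(scorer, bodypart, coord)].to_numpy(float) * px_to_m
    df = pd.DataFrame(out)
    df.insert(0, "frame", raw.index.to_numpy())
    return df


def write_marker_table(markers: pd.DataFrame, path,
                       dialect: str = "wide",
                       px_to_m: float = 1.0,
                       scorer: str = "quadgait") -> None:
    """Write a marker table in the wide or DeepLabCut-style dialect."""
    if dialect == "wide":
        markers.to_csv(path, index=False)
        return
    if dialect != "dlc":
        raise ValueError(f"unknown marker dialect {dialect!r}")
    cols = [c for c in markers.columns if c.endswith("_x") and c != "time_s"]
    header = pd.MultiIndex.from_tuples(
        [(scorer, c[:-2], "x") for c in cols],
        names=["scorer", "bodyparts", "coords"])
    body = pd.DataFrame(markers[cols].to_numpy() / px_to_m, columns=header)
    body.index.name = None
    body.to_csv(path, index=True)
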