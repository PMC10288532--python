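"""Synthetic quadrupedal gait generator.

Emulates treadmill footfall schedules with the statistical structure the
analysis assumes: stochastic hindlimb cycle durations, left-right hindlimb
alternation, homolateral fore-hind phase coupling drawn from a von Mises
distribution, and per-cycle coordination-ratio mixtures (1:1, 2:1, 1:2).
Matching sawtooth-like toe trajectories support the spatial measures. This
is a schedule generator, not a musculoskeletal or CPG simulation: cycles
are drawn independently and the swing trajectory shape is a free smooth
interpolant whose endpoints alone carry meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.interpolate import CubicHermiteSpline

from .events import FORELIMBS, HINDLIMBS, LIMBS, GaitEventTable, TrialMeta, from_times

RATIO_MODES = ("1:1", "2:1", "1:2")


class SyntheticGaitConfig(BaseModel):
    """Parameters of the synthetic gait generator.

    Defaults describe an intact cat walking on a tied-belt treadmill at
    0.4 m/s: hindlimb cycles around 0.85 s, duty factor 0.65, strict
    left-right hindlimb alternation, homolateral fore-hind phase near 90
    degrees with concentration kappa = 8, and pure 1:1 coordination.
    """

    model_config = ConfigDict(frozen=True)

    n_hind_cycles: int = Field(default=100, gt=0)
    hind_cycle_mean: float = Field(default=0.85, gt=0, description="seconds")
    hind_cycle_cv: float = Field(default=0.1, ge=0)
    duty_factor: dict[str, float] = Field(
        default_factory=lambda: {limb: 0.65 for limb in LIMBS})
    lr_hind_phase: float = Field(default=0.5, gt=0, lt=1)
    homolateral_phase_mean_deg: float = Field(default=90.0, ge=0, lt=360)
    phase_kappa: float = Field(default=8.0, ge=0)
    ratio_mix: dict[str, float] = Field(
        default_factory=lambda: {"1:1": 1.0, "2:1": 0.0, "1:2": 0.0})
    belt_speed: float = Field(default=0.4, gt=0, description="m/s")
    frame_rate: float = Field(
        default=0.0, ge=0,
        description="frames/s; 0 disables quantization of event times")
    stance_asym: float = Field(
        default=0.0,
        description="seconds added to right-side (RF, RH) stance durations")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if set(self.duty_factor) != set(LIMBS):
            raise ValueError(f"duty_factor must give all of {LIMBS}")
        for limb, d in self.duty_factor.items():
            if not (0.0 < d < 1.0):
                raise ValueError(f"duty factor for {limb} must be in (0,1), got {d}")
        if set(self.ratio_mix) - set(RATIO_MODES):
            raise ValueError(f"ratio_mix keys must be among {RATIO_MODES}")
        total = sum(self.ratio_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ratio_mix must sum to 1, got {total}")
        if any(p < 0 for p in self.ratio_mix.values()):
            raise ValueError("ratio_mix probabilities must be >= 0")
        return self


@dataclass(frozen=True)
class ScheduleTruth:
    """Ground truth recorded while generating a schedule (for verification).

    ``mode[i]`` is the coordination mode drawn for right-hindlimb cycle i
    ("1:2-second" marks the partner cycle that contains no forelimb
    contact); ``rf_phase_deg`` lists the von Mises phase drawn for each
    right-forelimb contact placement (the first contact in 2:1 cycles).
    """

    modes: list[str]
    rf_phase_deg: list[float]
    rh_contacts: np.ndarray
    rh_durations: np.ndarray


def _draw_cycle_durations(rng, n, mean, cv):
    if cv == 0:
        return np.full(n, mean, dtype=float)
    out = np.empty(n)
    for i in range(n):
        t = mean * (1.0 + cv * rng.standard_normal())
        while t <= 0:  # truncate to positive durations
            t = mean * (1.0 + cv * rng.standard_normal())
        out[i] = t
    return out


#: Concentrations at or above this are treated as a degenerate (point-mass)
#: von Mises distribution; the sampling jitter 1/sqrt(kappa) is below any
#: measurable phase resolution there anyway.
KAPPA_DEGENERATE = 1e6


def _von_mises_fraction(rng, mean_deg, kappa):
    """Draw a phase fraction in [0, 1) from a von Mises distribution."""
    if kappa == 0:
        ang = rng.uniform(-np.pi, np.pi)
    elif kappa >= KAPPA_DEGENERATE:
        ang = np.deg2rad(mean_deg)
    else:
        ang = rng.vonmises(np.deg2rad(mean_deg), kappa)
    return (ang / (2 * np.pi)) % 1.0, (np.rad2deg(ang) % 360.0)


def generate_event_schedule(config: SyntheticGaitConfig,
                            subject: str = "synthetic",
                            state: str = "intact") -> GaitEventTable:
    """Generate a validated footfall schedule. Deterministic given the seed."""
    table, _ = generate_event_schedule_with_truth(config, subject, state)
    return table


def generate_event_schedule_with_truth(
        config: SyntheticGaitConfig,
        subject: str = "synthetic",
        state: str = "intact") -> tuple[GaitEventTable, ScheduleTruth]:
    """Generate a schedule and the per-cycle ground truth used to build it.

    Construction, per right-hindlimb (RH) cycle of duration T:

    * LH contact at ``lr_hind_phase`` of the cycle;
    * mode 1:1 -- one RF contact at a von Mises phase of the cycle;
    * mode 2:1 -- two RF contacts, the second half a cycle after the first
      (phase wrapped into the cycle so both always fall inside it);
    * mode 1:2 -- one RF contact per two RH cycles (the forelimb cycle
      spans the pair); drawn at the last cycle with no partner it falls
      back to 1:1;
    * LF mirrors RF shifted by half the forelimb cycle;
    * liftoff at contact + duty_factor x own cycle, plus ``stance_asym``
      on right limbs; configs driving any stance or swing out of (0, cycle)
      are rejected.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_hind_cycles

    durations = _draw_cycle_durations(rng, n, cfg.hind_cycle_mean, cfg.hind_cycle_cv)
    rh_contacts = np.concatenate([[0.0], np.cumsum(durations)])

    mode_names = list(RATIO_MODES)
    mode_p = np.array([cfg.ratio_mix.get(m, 0.0) for m in mode_names])

    modes: list[str] = []
    rf_contacts: list[float] = []
    rf_phases: list[float] = []
    lh_contacts: list[float] = []

    i = 0
    while i < n:
        t0, T = rh_contacts[i], durations[i]
        lh_contacts.append(t0 + cfg.lr_hind_phase * T)
        mode = mode_names[int(rng.choice(len(mode_names), p=mode_p))]
        if mode == "1:2" and i + 1 >= n:
            mode = "1:1"  # no partner cycle left
        frac, deg = _von_mises_fraction(
            rng, cfg.homolateral_phase_mean_deg, cfg.phase_kappa)
        rf_phases.append(deg)
        if mode == "1:1":
            modes.append("1:1")
            rf_contacts.append(t0 + frac * T)
            i += 1
        elif mode == "2:1":
            modes.append("2:1")
            first = t0 + frac * T
            second = t0 + ((frac + 0.5) % 1.0) * T
            rf_contacts.extend(sorted((first, second)))
            i += 1
        else:  # 1:2 pair: one RF contact, forelimb cycle spans both RH cycles
            modes.extend(["1:2", "1:2-second"])
            rf_contacts.append(t0 + frac * T)
            lh_contacts.append(rh_contacts[i + 1]
                               + cfg.lr_hind_phase * durations[i + 1])
            i += 2

    rf = np.asarray(rf_contacts)
    lh = np.asarray(lh_contacts)
    if np.any(np.diff(rf) <= 0):
        raise ValueError("generated RF contacts are not strictly increasing; "
                         "reduce phase dispersion or cycle CV")
    # LF mirrors RF shifted by half of each RF cycle
    lf = rf[:-1] + 0.5 * np.diff(rf) if len(rf) > 1 else np.empty(0)

    contacts = {"RH": rh_contacts, "LH": lh, "RF": rf, "LF": lf}
    liftoffs: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        c = contacts[limb]
        if len(c) < 2:
            liftoffs[limb] = np.empty(0)
            continue
        own_cycles = np.diff(c)
        stance = cfg.duty_factor[limb] * own_cycles
        if limb in ("RF", "RH"):
            stance = stance + cfg.stance_asym
        if np.any(stance <= 0):
            raise ValueError(
                f"stance_asym={cfg.stance_asym} makes a {limb} stance <= 0")
        # the paw must lift before its next contact: in abnormally short
        # cycles (dispersed forelimb phases) the stance saturates at 95%
        # of the cycle instead of overrunning it
        stance = np.minimum(stance, 0.95 * own_cycles)
        liftoffs[limb] = c[:-1] + stance

    if cfg.frame_rate > 0:
        q = lambda t: np.round(np.asarray(t) * cfg.frame_rate) / cfg.frame_rate
        contacts = {k: q(v) for k, v in contacts.items()}
        liftoffs = {k: q(v) for k, v in liftoffs.items()}

    meta = TrialMeta(belt_speed=cfg.belt_speed, frame_rate=cfg.frame_rate,
                     subject=subject, state=state)
    table = from_times(contacts, liftoffs, meta)
    truth = ScheduleTruth(modes=modes, rf_phase_deg=rf_phases,
                          rh_contacts=rh_contacts, rh_durations=durations)
    return table, truth


#: Default body geometry for synthetic marker trajectories (meters on the
#: body-fixed fore-aft axis, positive rostral): hip at the origin, shoulder
#: one glenoacetabular distance ahead, toes landing slightly rostral of
#: their girdle.
DEFAULT_GIRDLE_X = {"hip": 0.0, "shoulder": 0.35}
DEFAULT_CONTACT_OFFSET = {"LF": 0.05, "RF": 0.05, "LH": 0.05, "RH": 0.05}


def generate_marker_trajectories(
        events: GaitEventTable,
        config: SyntheticGaitConfig,
        girdle_x: dict[str, float] | None = None,
        contact_offset: dict[str, float] | None = None) -> pd.DataFrame:
    """Synthesize horizontal toe/hip/shoulder marker trajectories.

    During stance the toe moves caudally with the belt at ``belt_speed``;
    during swing it returns along a smooth cubic to the next contact
    position. Hip and shoulder markers are held fixed. Contact positions
    are ``girdle_x + contact_offset`` per limb, so spatial measures on the
    output are known by construction. Requires ``frame_rate > 0``.

    Returns a wide MarkerTable DataFrame: ``time_s`` plus ``toe_<limb>_x``
    for the four limbs and ``shoulder_x`` / ``hip_x``.
    """
    fr = config.frame_rate
    if fr <= 0:
        raise ValueError("marker generation requires frame_rate > 0")
    girdle_x = dict(DEFAULT_GIRDLE_X if girdle_x is None else girdle_x)
    contact_offset = dict(DEFAULT_CONTACT_OFFSET
                          if contact_offset is None else contact_offset)

    t0, t1 = events.span
    n_frames = int(np.ceil((t1 - t0) * fr)) + 1
    time = t0 + np.arange(n_frames) / fr

    cols = {"time_s": time}
    for limb in LIMBS:
        girdle = girdle_x["shoulder" if limb in FORELIMBS else "hip"]
        x_contact = girdle + contact_offset[limb]
        cols[f"toe_{limb}_x"] = _toe_trajectory(
            time, events.contacts(limb), events.liftoffs(limb),
            x_contact, config.belt_speed)
    cols["shoulder_x"] = np.full_like(time, girdle_x["shoulder"])
    cols["hip_x"] = np.full_like(time, girdle_x["hip"])
    return pd.DataFrame(cols)


def _toe_trajectory(time, contacts, liftoffs, x_contact, belt_speed):
    """Piecewise toe position: linear caudal drift in stance, cubic swing."""
    x = np.full_like(time, x_contact, dtype=float)
    if len(contacts) == 0:
        return x
    # before the first contact, hold the landing position
    x[time < contacts[0]] = x_contact
    for i, c in enumerate(contacts):
        lo = liftoffs[(liftoffs >= c)]
        lo = lo[0] if len(lo) and (i + 1 >= len(contacts) or lo[0] < contacts[i + 1]) \
            else None
        end_of_stance = lo if lo is not None else time[-1]
        m = (time >= c) & (time <= end_of_stance)
        x[m] = x_contact - belt_speed * (time[m] - c)
        if lo is None:
            # trailing contact with no liftoff: stay in stance to the end
            m = time > end_of_stance
            x[m] = x_contact - belt_speed * (time[m] - c)
            break
        x_lift = x_contact - belt_speed * (lo - c)
        if i + 1 < len(contacts):
            nxt = contacts[i + 1]
            if nxt > lo:
                spline = CubicHermiteSpline(
                    [lo, nxt], [x_lift, x_contact],
                    [-belt_speed, -belt_speed])
                m = (time > lo) & (time < nxt)
                x[m] = spline(time[m])
        else:
            x[time > lo] = x_lift
    return x
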