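"""Fore-hind coordination classification and circular statistics.

Each hindlimb cycle (contact-to-contact, half-open window) is labelled by
the number of forelimb cycles it supports: 1:1 (one forelimb contact in the
window), 2:1 (two forelimb contacts -- the forelimb steps twice per
hindlimb cycle), or 1:2 (one forelimb cycle spans two hindlimb cycles, seen
after spinal transection). Phase intervals are forelimb contact latencies
normalized by the hindlimb cycle and expressed in degrees; their dispersion
is summarized by the mean resultant length r and Rayleigh's test z = n r^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import GaitEventTable

logger = logging.getLogger(__name__)

LABEL_11 = "1:1"
LABEL_21 = "2:1"
LABEL_12 = "1:2"
UNCLASSIFIED = "unclassified"

PHASE_LABELS = ("1:1", "2:1-first", "2:1-second", "1:2")


@dataclass(frozen=True)
class PhaseSample:
    """One forelimb contact's phase within its reference hindlimb cycle."""

    hind_cycle_idx: int
    fore_contact_s: float
    fraction: float  # in [0, 1)
    degrees: float   # fraction * 360, in [0, 360)
    label: str       # one of PHASE_LABELS


@dataclass(frozen=True)
class CircularSummary:
    """Circular summary of a sample of angles (degrees).

    r is the mean resultant length (1 = perfect concentration, 0 = uniform
    dispersion); z = n r^2 is Rayleigh's statistic, with p from the standard
    closed-form approximation and significance at alpha = 0.05.
    """

    n: int
    mean_deg: float
    r: float
    z: float
    p: float
    significant: bool


def classify_fore_hind(table: GaitEventTable,
                       fore: str = "RF",
                       hind: str = "RH") -> pd.DataFrame:
    """Label every hindlimb cycle by its fore-hind coordination ratio.

    Returns a DataFrame with columns ``cycle_idx, start_s, end_s,
    n_fore_contacts, label`` where label is 1:1, 2:1, 1:2 or
    ``unclassified`` (zero or more than two forelimb contacts with no
    spanning forelimb cycle). A hindlimb cycle with no forelimb contact
    whose window is covered by a single forelimb cycle is 1:2, together
    with the neighbouring hindlimb cycle containing that forelimb cycle's
    contact.
    """
    h = table.contacts(hind)
    f = table.contacts(fore)
    n_cycles = max(len(h) - 1, 0)
    counts = np.zeros(n_cycles, dtype=int)
    if len(f):
        idx = np.searchsorted(h, f, side="right") - 1
        for j in idx[(idx >= 0) & (idx < n_cycles)]:
            counts[j] += 1
    labels = []
    for k in counts:
        if k == 1:
            labels.append(LABEL_11)
        elif k == 2:
            labels.append(LABEL_21)
        else:
            labels.append(UNCLASSIFIED)

    # 1:2 pass, keyed on the forelimb: a forelimb cycle covering an empty
    # hindlimb cycle marks it and the cycle holding its contact as 1:2.
    for i in range(n_cycles):
        if counts[i] != 0:
            continue
        j = int(np.searchsorted(f, h[i], side="right")) - 1
        if j < 0 or j + 1 >= len(f):
            continue
        if f[j + 1] >= h[i + 1]:  # forelimb cycle spans the whole window
            labels[i] = LABEL_12
            i0 = int(np.searchsorted(h, f[j], side="right")) - 1
            if 0 <= i0 < n_cycles and labels[i0] == LABEL_11:
                labels[i0] = LABEL_12

    n_un = labels.count(UNCLASSIFIED)
    if n_un:
        logger.warning("%s/%s: %d of %d hindlimb cycles unclassified",
                       fore, hind, n_un, n_cycles)
    return pd.DataFrame({
        "cycle_idx": np.arange(n_cycles),
        "start_s": h[:-1] if n_cycles else np.empty(0),
        "end_s": h[1:] if n_cycles else np.empty(0),
        "n_fore_contacts": counts,
        "label": labels,
    })


@dataclass(frozen=True)
class Proportion2to1:
    """2:1 share among classified hindlimb cycles.

    ``percent`` is rounded half-up to an integer for reporting; the raw
    fraction is retained. ``percent`` and ``fraction`` are None when no
    cycle could be classified.
    """

    count_2to1: int
    total_classified: int
    fraction: float | None
    percent: int | None


def proportion_2to1(labels: pd.DataFrame) -> Proportion2to1:
    """Percentage of classified hindlimb cycles with 2:1 coordination."""
    classified = labels[labels["label"] != UNCLASSIFIED]
    total = len(classified)
    k = int((classified["label"] == LABEL_21).sum())
    if total == 0:
        logger.warning("no classified cycles; 2:1 proportion undefined")
        return Proportion2to1(k, 0, None, None)
    frac = k / total
    return Proportion2to1(k, total, frac, int(math.floor(100 * frac + 0.5)))


def proportion_of(labels: pd.DataFrame, label: str) -> Proportion2to1:
    """Share of classified cycles carrying an arbitrary label (e.g. 1:2)."""
    classified = labels[labels["label"] != UNCLASSIFIED]
    total = len(classified)
    k = int((classified["label"] == label).sum())
    if total == 0:
        return Proportion2to1(k, 0, None, None)
    frac = k / total
    return Proportion2to1(k, total, frac, int(math.floor(100 * frac + 0.5)))


def phase_intervals(table: GaitEventTable,
                    fore: str = "RF",
                    hind: str = "RH",
                    classification: pd.DataFrame | None = None
                    ) -> list[PhaseSample]:
    """Phase of every forelimb contact within its classified hindlimb cycle.

    The phase fraction is (forelimb contact - hindlimb contact) / hindlimb
    cycle duration in [0, 1), multiplied by 360 for degrees. In 2:1 cycles
    the two contacts yield separate samples labelled 2:1-first and
    2:1-second in time order; a 1:2 pair yields one sample (in the cycle
    holding the contact). Unclassified cycles yield none.
    """
    if classification is None:
        classification = classify_fore_hind(table, fore, hind)
    f = table.contacts(fore)
    samples: list[PhaseSample] = []
    for rec in classification.itertuples(index=False):
        if rec.label == UNCLASSIFIED:
            continue
        inside = f[(f >= rec.start_s) & (f < rec.end_s)]
        duration = rec.end_s - rec.start_s
        if rec.label == LABEL_21:
            sublabels = ("2:1-first", "2:1-second")
        elif rec.label == LABEL_11:
            sublabels = ("1:1",)
        else:  # 1:2 -- only the cycle containing the contact contributes
            sublabels = ("1:2",)
        for t, sub in zip(inside, sublabels):
            frac = (t - rec.start_s) / duration
            samples.append(PhaseSample(
                hind_cycle_idx=int(rec.cycle_idx),
                fore_contact_s=float(t),
                fraction=float(frac),
                degrees=float((frac * 360.0) % 360.0),
                label=sub,
            ))
    return samples


def phase_table(samples: list[PhaseSample], meta=None,
                pair: str = "RF/RH") -> pd.DataFrame:
    """Tidy DataFrame of phase samples (one row per forelimb contact)."""
    rows = [(getattr(meta, "subject", ""), getattr(meta, "state", ""),
             pair, s.label, s.hind_cycle_idx, s.degrees) for s in samples]
    return pd.DataFrame(rows, columns=["subject", "state", "pair", "label",
                                       "cycle_idx", "phase_deg"])


def rayleigh_p(n: int, z: float) -> float:
    """Closed-form approximation to the Rayleigh test p-value."""
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n * n - n * z)) - (1 + 2 * n))
    return min(max(p, 0.0), 1.0)


def circular_summary(degrees, alpha: float = 0.05) -> CircularSummary:
    """Mean direction, mean resultant length r, and Rayleigh z = n r^2.

    r is the magnitude of the mean of unit vectors at the sample angles;
    the mean direction is the argument of that vector mean (degrees in
    [0, 360)). Significance is p < alpha.
    """
    a = np.deg2rad(np.asarray(degrees, dtype=float).ravel())
    n = a.size
    if n == 0:
        raise ValueError("circular summary of an empty sample is undefined")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = float(np.hypot(c, s))
    mean_deg = float(np.rad2deg(np.arctan2(s, c)) % 360.0)
    z = n * r ** 2
    p = rayleigh_p(n, z)
    return CircularSummary(n=n, mean_deg=mean_deg, r=r, z=float(z), p=p,
                           significant=p < alpha)


def circular_summaries_by_label(samples: list[PhaseSample]
                                ) -> dict[str, CircularSummary]:
    """One circular summary per phase label present in the sample."""
    out: dict[str, CircularSummary] = {}
    for label in PHASE_LABELS:
        degs = [s.degrees for s in samples if s.label == label]
        if degs:
            out[label] = circular_summary(degs)
    return out
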