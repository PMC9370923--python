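"""Gait-event detection: label TO, MSV and HS timestamps on the smoothed signal.

Convention (the one that makes swing/stance/stride durations positive): each
dominant positive peak of the shank signal is the max-swing-velocity (MSV)
event; the nearest trough before it is toe-off (TO) and the nearest trough
after it is heel strike (HS).  Incomplete leading/trailing cycles, and cycles
that would break the global TO < MSV < HS < next-TO ordering, are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InsufficientGaitError, InvalidEventsError, SignalTooShortError
from .preprocess import CleanSignal

DEFAULT_PROMINENCE_FRAC = 0.5
DEFAULT_SEPARATION_S = 0.25


@dataclass
class Extrema:
    """Candidate peak/trough times (seconds, absolute) from one signal."""

    peak_times: np.ndarray
    trough_times: np.ndarray

    @property
    def n_candidates(self) -> int:
        return len(self.peak_times) + len(self.trough_times)


@dataclass
class EventSeries:
    """Labeled gait events for one foot, cycle-ordered.

    Per cycle n the invariant TO(n) < MSV(n) < HS(n) < TO(n+1) holds.
    """

    subject_id: str
    foot: str
    task: str
    to_s: np.ndarray
    msv_s: np.ndarray
    hs_s: np.ndarray

    def __post_init__(self) -> None:
        self.to_s = np.asarray(self.to_s, dtype=float)
        self.msv_s = np.asarray(self.msv_s, dtype=float)
        self.hs_s = np.asarray(self.hs_s, dtype=float)
        if not (len(self.to_s) == len(self.msv_s) == len(self.hs_s)):
            raise InvalidEventsError("per-cycle event arrays must have equal length")
        if len(self.msv_s) and not (
            np.all(self.to_s < self.msv_s)
            and np.all(self.msv_s < self.hs_s)
            and np.all(self.hs_s[:-1] < self.to_s[1:])
        ):
            raise InvalidEventsError("events must satisfy TO < MSV < HS < next TO")

    @property
    def n_cycles(self) -> int:
        return len(self.msv_s)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in range(self.n_cycles):
            rows.append((n, "TO", self.to_s[n]))
            rows.append((n, "MSV", self.msv_s[n]))
            rows.append((n, "HS", self.hs_s[n]))
        return pd.DataFrame(rows, columns=["cycle", "label", "time_s"])


def detect_extrema(
    sig: CleanSignal,
    min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation_s: float = DEFAULT_SEPARATION_S,
) -> Extrema:
    """Local maxima/minima with both amplitude and prominence >= frac x signal
    SD (computed on the mean-centered signal), separated in time.

    The amplitude criterion rejects the shallow stance-phase ripples between a
    heel-strike trough and the next toe-off trough, which are prominent
    relative to their flanking troughs but sit near the baseline.
    """
    if sig.duration < 2.0:
        raise SignalTooShortError("need >= 2 s of signal for event detection")
    x = sig.samples - np.mean(sig.samples)
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return Extrema(np.array([]), np.array([]))
    threshold = min_prominence_frac * sd
    distance = max(1, int(round(min_separation_s * sig.sampling_rate)))
    pk, _ = find_peaks(x, height=threshold, prominence=threshold, distance=distance)
    tr, _ = find_peaks(-x, height=threshold, prominence=threshold, distance=distance)
    t = sig.times
    return Extrema(peak_times=t[pk], trough_times=t[tr])


def label_events(candidates: Extrema, sig: CleanSignal) -> EventSeries:
    """Assign MSV/TO/HS labels to candidate extrema.

    Each peak becomes an MSV anchored by its nearest preceding trough (TO) and
    nearest following trough (HS).  Peaks lacking a flanking trough, and
    cycles that would reuse a trough already consumed by the previous cycle,
    are dropped.
    """
    if candidates.n_candidates < 3:
        raise InsufficientGaitError(
            f"need >= 3 candidate extrema, got {candidates.n_candidates}"
        )
    troughs = candidates.trough_times
    cycles: list[tuple[float, float, float]] = []
    for p in candidates.peak_times:
        i = np.searchsorted(troughs, p)
        if i == 0 or i == len(troughs):
            continue  # incomplete leading/trailing cycle
        to, hs = troughs[i - 1], troughs[i]
        if cycles and to <= cycles[-1][2]:
            continue  # would share/overlap the previous cycle's HS trough
        cycles.append((to, p, hs))
    if len(cycles) < 2:
        raise InsufficientGaitError(f"found {len(cycles)} complete cycles; need >= 2")
    arr = np.array(cycles)
    return EventSeries(
        subject_id=sig.subject_id,
        foot=sig.foot,
        task=sig.task,
        to_s=arr[:, 0],
        msv_s=arr[:, 1],
        hs_s=arr[:, 2],
    )


def detect_events(
    sig: CleanSignal,
    min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation_s: float = DEFAULT_SEPARATION_S,
) -> EventSeries:
    """Convenience: detect extrema then label them."""
    return label_events(
        detect_extrema(sig, min_prominence_frac, min_separation_s), sig
    )


def write_events(ev: EventSeries, path) -> None:
    df = ev.to_frame()
    df.insert(0, "task", ev.task)
    df.insert(0, "foot", ev.foot)
    df.insert(0, "subject_id", ev.subject_id)
    df.to_csv(path, index=False)
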