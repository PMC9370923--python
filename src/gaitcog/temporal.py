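"""Temporal gait parameters: swing/stance/stride times, turn removal, velocity, CoV.

Definitions (per cycle n of an EventSeries):

    swing(n)  = HS(n)   - TO(n)
    stance(n) = TO(n+1) - HS(n)
    stride(n) = MSV(n+1) - MSV(n)

The turning artifact — the anomalously long pseudo-stride where the subject
turns around mid-walk — is removed by flagging durations deviating more than
two sample standard deviations from the series mean (single pass, applied
independently to the swing, stance and stride series).

Walking velocity is 20 m divided by the total walking time; by default the
trimmed recording duration (which includes the turn) is used, matching the
manual-trim convention; the events-only span is available as an alternative.
Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GaitcogError, InvalidParameterError
from .events import EventSeries
from .preprocess import CleanSignal

WALK_DISTANCE_M = 20.0
TURN_SD_THRESHOLD = 2.0
MAX_PLAUSIBLE_STRIDE_S = 5.0


@dataclass
class StrideTable:
    """Per-cycle durations with turn-outlier flags.

    For k complete cycles there are k swing times and k-1 stance/stride times.
    """

    subject_id: str
    foot: str
    task: str
    swing_s: np.ndarray
    stance_s: np.ndarray
    stride_s: np.ndarray
    swing_removed: np.ndarray = field(default=None)
    stance_removed: np.ndarray = field(default=None)
    stride_removed: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.swing_s = np.asarray(self.swing_s, dtype=float)
        self.stance_s = np.asarray(self.stance_s, dtype=float)
        self.stride_s = np.asarray(self.stride_s, dtype=float)
        for name in ("swing", "stance", "stride"):
            flags = getattr(self, f"{name}_removed")
            vals = getattr(self, f"{name}_s")
            if flags is None:
                setattr(self, f"{name}_removed", np.zeros(len(vals), dtype=bool))

    def retained(self, series: str) -> np.ndarray:
        vals = getattr(self, f"{series}_s")
        return vals[~getattr(self, f"{series}_removed")]

    @property
    def n_removed(self) -> int:
        return int(
            self.swing_removed.sum() + self.stance_removed.sum() + self.stride_removed.sum()
        )

    def to_frame(self) -> pd.DataFrame:
        k = len(self.swing_s)
        df = pd.DataFrame({"cycle": np.arange(k), "swing_s": self.swing_s})
        df["stance_s"] = np.append(self.stance_s, np.nan)
        df["stride_s"] = np.append(self.stride_s, np.nan)
        df["swing_removed"] = self.swing_removed
        df["stance_removed"] = np.append(self.stance_removed, False)
        df["stride_removed"] = np.append(self.stride_removed, False)
        return df


@dataclass
class GaitSummary:
    """One row of the per-walk summary table (Table-4-style structure)."""

    subject_id: str
    foot: str
    task: str
    velocity_mps: float
    swing_s: float
    stance_s: float
    stride_s: float
    cov_pct: float
    complexity: float
    n_removed: int


def stride_intervals(ev: EventSeries) -> StrideTable:
    """Swing, stance and stride durations from a labeled event series."""
    if ev.n_cycles < 2:
        raise GaitcogError("need >= 2 complete cycles for stride intervals")
    swing = ev.hs_s - ev.to_s
    stance = ev.to_s[1:] - ev.hs_s[:-1]
    stride = np.diff(ev.msv_s)
    if np.any(swing <= 0) or np.any(stance <= 0) or np.any(stride <= 0):
        raise GaitcogError("event ordering violation: non-positive duration")
    return StrideTable(
        subject_id=ev.subject_id,
        foot=ev.foot,
        task=ev.task,
        swing_s=swing,
        stance_s=stance,
        stride_s=stride,
    )


def _flag_outliers(values: np.ndarray, n_sd: float) -> np.ndarray:
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0.0:
        return np.zeros(len(values), dtype=bool)
    return np.abs(values - mean) > n_sd * sd


def remove_turn_artifact(tbl: StrideTable, n_sd: float = TURN_SD_THRESHOLD) -> StrideTable:
    """Flag durations more than ``n_sd`` sample SDs from the mean (single pass).

    Mean and SD are computed over the unfiltered series.  Series with fewer
    than 3 values are left untouched with a warning.
    """
    out = replace(tbl)
    for name in ("swing", "stance", "stride"):
        vals = getattr(tbl, f"{name}_s")
        if len(vals) < 3:
            warnings.warn(
                f"{name} series has {len(vals)} values; turn removal skipped",
                stacklevel=2,
            )
            continue
        setattr(out, f"{name}_removed", _flag_outliers(vals, n_sd))
    return out


def walk_velocity(total_time_s: float, distance_m: float = WALK_DISTANCE_M) -> float:
    """Average walking velocity: distance (20 m) over total walking time."""
    if total_time_s <= 0:
        raise InvalidParameterError("total walking time must be positive")
    return distance_m / total_time_s


def cov(stride_times: np.ndarray) -> float:
    """Coefficient of variation of stride times: 100 x sample SD / mean (percent)."""
    x = np.asarray(stride_times, dtype=float)
    if len(x) < 2:
        raise InvalidParameterError("CoV needs >= 2 stride times")
    mean = x.mean()
    if mean == 0.0:
        raise InvalidParameterError("CoV undefined for zero-mean stride times")
    return 100.0 * x.std(ddof=1) / mean


def summarize(
    clean: CleanSignal,
    ev: EventSeries,
    tbl: StrideTable,
    complexity: float,
    velocity_from: str = "recording",
) -> GaitSummary:
    """Assemble one per-walk summary row; means are taken after turn removal.

    ``velocity_from`` is "recording" (trimmed duration, turn included) or
    "events" (first-TO-to-last-HS span).
    """
    if clean is None or ev is None or tbl is None:
        raise GaitcogError("incomplete summary: missing component")
    if velocity_from == "recording":
        total = clean.duration
    elif velocity_from == "events":
        total = float(ev.hs_s[-1] - ev.to_s[0])
    else:
        raise InvalidParameterError(f"unknown velocity_from: {velocity_from!r}")
    strides = tbl.retained("stride")
    return GaitSummary(
        subject_id=clean.subject_id,
        foot=clean.foot,
        task=clean.task,
        velocity_mps=walk_velocity(total),
        swing_s=float(tbl.retained("swing").mean()),
        stance_s=float(tbl.retained("stance").mean()),
        stride_s=float(strides.mean()),
        cov_pct=cov(strides),
        complexity=float(complexity),
        n_removed=tbl.n_removed,
    )
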