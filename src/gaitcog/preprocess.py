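"""Raw shank-signal conditioning: trim, downsample to 200 Hz, median + Butterworth smoothing.

The processing chain is fixed: trim -> resample -> median filter (window 5)
-> 4th-order Butterworth low-pass.  The low-pass is applied forward-backward
(zero phase) so that event timestamps downstream are not lagged by the filter;
gait energy lies below ~10 Hz, the default cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import (
    InvalidParameterError,
    SignalTooShortError,
    UnsupportedRateError,
)

TARGET_RATE_HZ = 200.0
DEFAULT_CUTOFF_HZ = 10.0
MEDIAN_WINDOW = 5
BUTTER_ORDER = 4
#: minimum samples for the smoothing filters to warm up
MIN_SMOOTH_SAMPLES = 15


@dataclass
class RawRecording:
    """Uniformly sampled shank motion signal for one subject/foot/task.

    ``samples`` is either 1-D ``(n,)`` or 3-axis ``(n, 3)``.
    """

    subject_id: str
    foot: str
    task: str
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.samples.size == 0:
            raise InvalidParameterError("samples must be non-empty")
        if self.samples.ndim not in (1, 2):
            raise InvalidParameterError("samples must be 1-D or (n, 3)")
        if self.samples.ndim == 2 and self.samples.shape[1] != 3:
            raise InvalidParameterError("multi-axis samples must have 3 columns")
        if self.foot not in ("left", "right"):
            raise InvalidParameterError(f"foot must be left|right, got {self.foot!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class CleanSignal:
    """Smoothed single-axis signal at exactly 200 Hz, ready for event detection."""

    subject_id: str
    foot: str
    task: str
    samples: np.ndarray
    start_time: float = 0.0
    sampling_rate: float = TARGET_RATE_HZ
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


def trim(rec: RawRecording, t_start: float, t_end: float) -> RawRecording:
    """Keep the closed-open window [t_start, t_end), in seconds from recording start."""
    if not (0.0 <= t_start < t_end <= rec.duration + 0.5 / rec.sampling_rate):
        raise InvalidParameterError(
            f"trim window [{t_start}, {t_end}) outside recording of {rec.duration:.3f} s"
        )
    i0 = int(round(t_start * rec.sampling_rate))
    i1 = int(round(t_end * rec.sampling_rate))
    i1 = min(i1, rec.n_samples)
    return replace(
        rec,
        samples=rec.samples[i0:i1].copy(),
        start_time=rec.start_time + i0 / rec.sampling_rate,
    )


def resample_to_200hz(rec: RawRecording) -> RawRecording:
    """Downsample to 200 Hz with polyphase anti-aliasing; no upsampling.

    The input rate must be >= 200 Hz and a rational multiple of 200.
    """
    if rec.sampling_rate < TARGET_RATE_HZ:
        raise UnsupportedRateError(
            f"cannot upsample {rec.sampling_rate} Hz to {TARGET_RATE_HZ} Hz"
        )
    if rec.sampling_rate == TARGET_RATE_HZ:
        return replace(rec, samples=rec.samples.copy())
    ratio = Fraction(rec.sampling_rate / TARGET_RATE_HZ).limit_denominator(1000)
    up, down = ratio.denominator, ratio.numerator
    out = sps.resample_poly(rec.samples, up, down, axis=0)
    return replace(rec, samples=out, sampling_rate=TARGET_RATE_HZ)


def select_axis(samples: np.ndarray, axis: int | str = "auto") -> np.ndarray:
    """Reduce a 3-axis block to the analysis axis.

    ``"auto"`` picks the axis with the greatest variance over the walk (the
    sagittal-plane axis dominates during straight walking).
    """
    if samples.ndim == 1:
        return samples
    if axis == "auto":
        axis = int(np.argmax(np.var(samples, axis=0)))
    return samples[:, int(axis)]


def smooth(
    rec: RawRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    axis: int | str = "auto",
) -> CleanSignal:
    """Median filter (window 5) then zero-phase 4th-order Butterworth low-pass."""
    if rec.sampling_rate != TARGET_RATE_HZ:
        raise UnsupportedRateError("smooth() expects a 200 Hz recording; resample first")
    x = select_axis(rec.samples, axis)
    if x.shape[0] < MIN_SMOOTH_SAMPLES:
        raise SignalTooShortError(
            f"need >= {MIN_SMOOTH_SAMPLES} samples for filtering, got {x.shape[0]}"
        )
    # reflect-pad so the window-5 median does not fabricate boundary extremes
    pad = MEDIAN_WINDOW // 2
    xp = np.pad(x, pad, mode="reflect")
    med = sps.medfilt(xp, kernel_size=MEDIAN_WINDOW)[pad:-pad]
    sos = sps.butter(BUTTER_ORDER, cutoff_hz, btype="low", fs=rec.sampling_rate, output="sos")
    out = sps.sosfiltfilt(sos, med)
    return CleanSignal(
        subject_id=rec.subject_id,
        foot=rec.foot,
        task=rec.task,
        samples=out,
        start_time=rec.start_time,
        provenance={
            "median_window": MEDIAN_WINDOW,
            "butter_order": BUTTER_ORDER,
            "cutoff_hz": cutoff_hz,
            "zero_phase": True,
        },
    )


def preprocess(
    rec: RawRecording,
    t_start: float | None = None,
    t_end: float | None = None,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    axis: int | str = "auto",
) -> CleanSignal:
    """Full conditioning chain: trim -> resample -> median -> Butterworth."""
    if t_start is not None or t_end is not None:
        rec = trim(rec, t_start or 0.0, t_end if t_end is not None else rec.duration)
    rec = resample_to_200hz(rec)
    return smooth(rec, cutoff_hz=cutoff_hz, axis=axis)
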