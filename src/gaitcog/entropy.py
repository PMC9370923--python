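"""Multiscale entropy (MSE) and the complexity index.

Sample entropy SE(m, r) is the negative log conditional probability that two
sequences matching for m points (Chebyshev distance <= r, self-matches
excluded) also match for m+1 points.  Multiscale entropy computes SE on
coarse-grained (non-overlapping block-mean) versions of the signal at scales
tau = 1..tau_max; the area under the SE-vs-scale curve is the complexity
index.  Regular, predictable signals score low; signals with structure across
many timescales (e.g. 1/f noise) score higher than white noise.

Conventions: natural-log units; the tolerance r is a fraction of the SD of
the scale-1 (original) series and the resulting absolute tolerance is reused
at every scale, so the index is invariant to affine rescaling of the input.
Scales whose coarse series is shorter than 10*m, or where no (m+1)-length
match exists, are marked invalid and excluded from the area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GaitcogError, InvalidParameterError, SignalTooShortError

DEFAULT_M = 2
DEFAULT_R = 0.2
DEFAULT_TAU_MAX = 40
#: minimum coarse-series length (in multiples of m) for a scale to be valid
MIN_LENGTH_FACTOR = 10


@dataclass(frozen=True)
class SampEnParams:
    """m = template length, r = tolerance as a fraction of the scale-1 SD."""

    m: int = DEFAULT_M
    r: float = DEFAULT_R
    tau_max: int = DEFAULT_TAU_MAX

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidParameterError("m must be >= 1")
        if not (0.0 < self.r < 1.0):
            raise InvalidParameterError("r must be in (0, 1)")
        if self.tau_max < 1:
            raise InvalidParameterError("tau_max must be >= 1")


@dataclass
class MSECurve:
    """Sample entropy per scale and the resulting complexity index."""

    scales: np.ndarray
    lengths: np.ndarray
    se: np.ndarray
    valid: np.ndarray
    params: SampEnParams
    complexity_index: float = field(default=np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scale": self.scales, "length": self.lengths, "se": self.se, "valid": self.valid}
        )


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length tau; the remainder is dropped."""
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise InvalidParameterError("tau must be >= 1")
    if tau > len(x):
        raise InvalidParameterError(f"tau={tau} exceeds series length {len(x)}")
    if tau == 1:
        return x.copy()
    n = len(x) // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def sample_entropy(x: np.ndarray, m: int = DEFAULT_M, r_abs: float | None = None) -> float:
    """Sample entropy in nats; NaN when no (m+1)-length template pair matches.

    ``r_abs`` is the absolute Chebyshev tolerance.  Counting follows the
    standard convention: both template lengths use the N-m start positions
    0..N-m-1, and self-matches are excluded.
    """
    x = np.asarray(x, dtype=float)
    N = len(x)
    if N < m + 2:
        raise SignalTooShortError(f"need >= m+2 = {m + 2} points, got {N}")
    if r_abs is None or r_abs <= 0:
        raise InvalidParameterError("r_abs must be a positive absolute tolerance")
    P = N - m
    D = np.abs(x[:, None] - x[None, :]) <= r_abs
    match = D[:P, :P].copy()
    for k in range(1, m):
        match &= D[k : k + P, k : k + P]
    b = int(match.sum()) - P
    match &= D[m : m + P, m : m + P]
    a = int(match.sum()) - P
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_curve(x: np.ndarray, params: SampEnParams = SampEnParams()) -> MSECurve:
    """Multiscale entropy over scales 1..tau_max with a fixed absolute tolerance."""
    x = np.asarray(x, dtype=float)
    if len(x) < params.m + 2:
        raise SignalTooShortError("series too short for scale-1 sample entropy")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise InvalidParameterError("constant series: tolerance would be zero")
    r_abs = params.r * sd

    scales = np.arange(1, params.tau_max + 1)
    lengths = np.array([len(x) // tau for tau in scales])
    se = np.full(len(scales), np.nan)
    valid = np.zeros(len(scales), dtype=bool)
    for i, tau in enumerate(scales):
        if lengths[i] < MIN_LENGTH_FACTOR * params.m:
            continue
        val = sample_entropy(coarse_grain(x, int(tau)), params.m, r_abs)
        se[i] = val
        valid[i] = np.isfinite(val)
    if not valid.any():
        raise GaitcogError("all scales invalid: no defined sample entropy")
    n_invalid = int((~valid).sum())
    if n_invalid:
        warnings.warn(
            f"{n_invalid}/{len(scales)} scales invalid and excluded from the area",
            stacklevel=2,
        )
    curve = MSECurve(scales=scales, lengths=lengths, se=se, valid=valid, params=params)
    if valid.sum() >= 2:
        curve.complexity_index = complexity_index(curve)
    return curve


def complexity_index(curve: MSECurve) -> float:
    """Trapezoidal area of SE over the valid scales (scale axis in units of tau)."""
    mask = curve.valid
    if mask.sum() < 2:
        raise GaitcogError("complexity index needs >= 2 valid scales")
    return float(np.trapezoid(curve.se[mask], curve.scales[mask]))
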