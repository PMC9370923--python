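import numpy as np
import pytest

from gaitcog.preprocess import CleanSignal
from gaitcog.synthetic import StrideParams, simulate_walk


@pytest.fixture(scope="session")
def quiet_walk():
    """Noise-free, jitter-free walk at the control-group defaults."""
    return simulate_walk(
        StrideParams(noise_sd=0.0, stride_jitter_cov=0.0), seed=7, subject_id="quiet"
    )


@pytest.fixture(scope="session")
def jittered_walk():
    """Noise-free walk with 3% stride-time jitter."""
    return simulate_walk(
        StrideParams(noise_sd=0.0, stride_jitter_cov=3.0), seed=11, subject_id="jit"
    )


def as_clean(x, fs=200.0, subject="t", foot="left", task="normal"):
    """Wrap a bare array as a CleanSignal for event-detection tests."""
    return CleanSignal(
        subject_id=subject, foot=foot, task=task, samples=np.asarray(x, dtype=float),
        sampling_rate=fs,
    )


def match_errors(detected: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-truth-event distance (s) to the nearest detected event."""
    return np.abs(truth[:, None] - detected[None, :]).min(axis=1)
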