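"""Reading and writing the plain-text recording format.

Recordings are delimited tables with columns ``time_s, ax, ay, az`` written
by :mod:`gaitcog.synthetic`; the sampling rate is inferred from the median
time step and sampling must be uniform within 1% jitter.  Filenames follow
``<subject>_<foot>_<task>.csv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .preprocess import RawRecording

REQUIRED_COLUMNS = ("time_s", "ax", "ay", "az")
MAX_DT_JITTER = 0.01


def recording_filename(subject_id: str, foot: str, task: str) -> str:
    return f"{subject_id}_{foot}_{task}.csv"


def parse_recording_filename(path: str | Path) -> tuple[str, str, str]:
    parts = Path(path).stem.split("_")
    if len(parts) < 3:
        raise FormatError(f"cannot parse subject/foot/task from {path}")
    return "_".join(parts[:-2]), parts[-2], parts[-1]


def load_recording(
    path: str | Path,
    subject_id: str | None = None,
    foot: str | None = None,
    task: str | None = None,
) -> RawRecording:
    """Load and validate a tabular recording; rate inferred from median dt."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap as a format error
        raise FormatError(f"{path}: unreadable recording ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > MAX_DT_JITTER * med:
        raise FormatError(f"{path}: non-uniform sampling beyond 1% jitter")
    if subject_id is None or foot is None or task is None:
        psub, pfoot, ptask = parse_recording_filename(path)
        subject_id = subject_id or psub
        foot = foot or pfoot
        task = task or ptask
    samples = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    return RawRecording(
        subject_id=subject_id,
        foot=foot,
        task=task,
        sampling_rate=1.0 / med,
        samples=samples,
        start_time=float(t[0]),
    )
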