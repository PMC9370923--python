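"""Synthetic shank-signal walks and cohorts with known ground truth.

The generator emulates the 20 m clinical walk protocol (10 m, turn around,
10 m) recorded by a shank-worn inertial sensor at ~200 Hz.  Each gait cycle is
a periodic waveform with one dominant positive mid-swing peak (max swing
velocity, MSV) flanked by a toe-off (TO) trough before and a heel-strike (HS)
trough after — the morphology event detection relies on.  The turn is a single
low-amplitude sway segment without gait events, so downstream it appears as
exactly one long pseudo-stride, the artifact the 2-SD removal rule targets.

Cohort defaults encode the study conditions of a midlife type 2 diabetes
(T2DM) gait cohort: 44 healthy controls vs 94 T2DM, with the T2DM group
walking slower, with longer stride times and a noisier (more complex) signal,
and global cognition (MoCA) linearly coupled to walking velocity.

Notes on construction
---------------------
* MSV timestamps are laid down first as a jittered renewal process, so true
  stride times (MSV-to-MSV) have exactly the requested coefficient of
  variation.  Swing is held constant within a walk and the cycle is anchored
  at MSV (TO = MSV - swing/2, HS = MSV + swing/2); stride-time jitter is
  therefore carried by the stance phase and the telescoping identity
  stride = swing + stance holds exactly.
* The stride count is the nearest integer to 20 m / (velocity x stride time)
  and the nominal stride time is rescaled so that, with zero jitter, total
  walking time is exactly 20 m / velocity.
* All event times are snapped to the sample grid, so noise-free detection can
  recover them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UnsupportedRateError
from .preprocess import RawRecording

WALK_DISTANCE_M = 20.0
TASKS = ("normal", "fast", "dual")
FEET = ("left", "right")

#: lobe widths relative to swing time; troughs are narrower than the MSV peak
_MSV_SIGMA_FRAC = 0.10
_TROUGH_SIGMA_FRAC = 0.05
_TROUGH_DEPTH = 0.6
_TURN_AMP_FRAC = 0.1


@dataclass(frozen=True)
class StrideParams:
    """Per-walk gait parameters.

    stride_jitter_cov is the coefficient of variation of stride times in
    percent; noise_sd is additive white-noise SD in signal units.
    """

    swing_s: float = 0.50
    stance_s: float = 0.51
    velocity_mps: float = 1.35
    amplitude: float = 1.0
    noise_sd: float = 0.05
    stride_jitter_cov: float = 3.0

    def __post_init__(self) -> None:
        if self.swing_s <= 0 or self.stance_s <= 0:
            raise InvalidParameterError("swing_s and stance_s must be positive")
        if self.velocity_mps <= 0:
            raise InvalidParameterError("velocity_mps must be positive")
        if self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be positive")
        if self.noise_sd < 0 or self.stride_jitter_cov < 0:
            raise InvalidParameterError("noise_sd and stride_jitter_cov must be >= 0")

    @property
    def stride_s(self) -> float:
        return self.swing_s + self.stance_s


@dataclass
class GroundTruth:
    """True events and timing for one simulated walk.

    Event arrays cover every real gait cycle (the turn has none).  The stride
    interval spanning the turn is excluded from ``stride_times_s``;
    ``velocity_mps`` is 20 m divided by the summed true stride times.
    """

    to_s: np.ndarray
    msv_s: np.ndarray
    hs_s: np.ndarray
    turn_start_s: float
    turn_end_s: float
    stride_times_s: np.ndarray
    velocity_mps: float

    def __post_init__(self) -> None:
        for name in ("to_s", "msv_s", "hs_s", "stride_times_s"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (np.all(self.to_s < self.msv_s) and np.all(self.msv_s < self.hs_s)):
            raise InvalidParameterError("ground truth must satisfy TO < MSV < HS per cycle")
        for arr in (self.to_s, self.msv_s, self.hs_s):
            if np.any(np.diff(arr) <= 0):
                raise InvalidParameterError("ground-truth event times must be increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.msv_s)

    def event_frame(self) -> pd.DataFrame:
        rows = []
        for n in range(self.n_cycles):
            rows.append((n, "TO", self.to_s[n]))
            rows.append((n, "MSV", self.msv_s[n]))
            rows.append((n, "HS", self.hs_s[n]))
        return pd.DataFrame(rows, columns=["cycle", "label", "time_s"])


def _gauss_lobes(t: np.ndarray, centers, amps, sigmas) -> np.ndarray:
    """Sum of Gaussian lobes, each evaluated only on its +-5 sigma window."""
    out = np.zeros_like(t)
    dt = t[1] - t[0]
    for c, a, s in zip(centers, amps, sigmas):
        i0 = max(0, int((c - 5 * s - t[0]) / dt))
        i1 = min(len(t), int((c + 5 * s - t[0]) / dt) + 2)
        if i1 > i0:
            out[i0:i1] += a * np.exp(-0.5 * ((t[i0:i1] - c) / s) ** 2)
    return out


def make_stride_waveform(
    params: StrideParams, fs: float = 200.0, rng_seed: int | None = None
) -> tuple[np.ndarray, dict[str, float]]:
    """One-cycle template and within-cycle event offsets (seconds).

    The cycle spans [0, swing+stance): a TO trough at (T-swing)/2, the MSV
    peak mid-cycle and an HS trough at (T+swing)/2, all snapped to the sample
    grid.  With noise_sd = 0 the discrete extrema coincide with the offsets.
    """
    if fs < 50:
        raise UnsupportedRateError(f"fs must be >= 50 Hz to resolve events, got {fs}")
    T = params.stride_s
    n = int(round(T * fs))
    snap = lambda x: round(x * fs) / fs
    offsets = {
        "TO": snap((T - params.swing_s) / 2),
        "MSV": snap(T / 2),
        "HS": snap((T + params.swing_s) / 2),
    }
    t = np.arange(n) / fs
    a = params.amplitude
    sig = _gauss_lobes(
        t,
        [offsets["TO"], offsets["MSV"], offsets["HS"]],
        [-_TROUGH_DEPTH * a, a, -_TROUGH_DEPTH * a],
        [
            _TROUGH_SIGMA_FRAC * params.swing_s,
            _MSV_SIGMA_FRAC * params.swing_s,
            _TROUGH_SIGMA_FRAC * params.swing_s,
        ],
    )
    if rng_seed is not None and params.noise_sd > 0:
        sig = sig + np.random.default_rng(rng_seed).normal(0, params.noise_sd, n)
    return sig, offsets


def simulate_walk(
    params: StrideParams,
    task: str = "normal",
    fs: float = 200.0,
    seed: int | None = None,
    turn_s: float = 3.0,
    pad_s: float = 0.4,
    subject_id: str = "sim",
    foot: str = "left",
) -> tuple[RawRecording, GroundTruth]:
    """Simulate one 20 m walk (10 m, turn, 10 m) with known events.

    The turn is a low-amplitude sway bump of duration ``turn_s`` between the
    two straights; the MSV-to-MSV interval spanning it is the turning
    pseudo-stride.
    """
    if fs < 50:
        raise UnsupportedRateError(f"fs must be >= 50 Hz to resolve events, got {fs}")
    if turn_s <= params.swing_s + 0.3:
        raise InvalidParameterError("turn_s must exceed the swing time comfortably")
    rng = np.random.default_rng(seed)

    T_req = params.stride_s
    n_strides = max(2, int(round(WALK_DISTANCE_M / (params.velocity_mps * T_req))))
    T = WALK_DISTANCE_M / (params.velocity_mps * n_strides)  # adjusted nominal stride
    swing = params.swing_s * (T / T_req)
    half_swing = round(swing / 2 * fs) / fs
    n1 = n_strides // 2
    n2 = n_strides - n1

    jitter = params.stride_jitter_cov / 100.0
    s1 = T * (1.0 + jitter * rng.standard_normal(n1))
    s2 = T * (1.0 + jitter * rng.standard_normal(n2))
    s1 = np.clip(s1, 0.5 * T, 1.5 * T)
    s2 = np.clip(s2, 0.5 * T, 1.5 * T)

    msv0 = pad_s + half_swing + 0.1
    msv_a = msv0 + np.concatenate([[0.0], np.cumsum(s1)])      # n1 + 1 anchors
    msv_b = msv_a[-1] + turn_s + np.concatenate([[0.0], np.cumsum(s2)])
    msv = np.concatenate([msv_a, msv_b])
    msv = np.round(msv * fs) / fs                               # snap to grid
    to = msv - half_swing
    hs = msv + half_swing

    spanning = n1  # index of the stride interval that crosses the turn
    all_strides = np.diff(msv)
    stride_times = np.delete(all_strides, spanning)
    velocity = WALK_DISTANCE_M / float(stride_times.sum())
    turn_start = hs[n1]
    turn_end = to[n1 + 1]

    dur = hs[-1] + half_swing + pad_s
    n_samp = int(round(dur * fs))
    t = np.arange(n_samp) / fs

    a = params.amplitude
    centers = np.concatenate([to, msv, hs])
    amps = np.concatenate(
        [np.full(len(to), -_TROUGH_DEPTH * a), np.full(len(msv), a), np.full(len(hs), -_TROUGH_DEPTH * a)]
    )
    sigmas = np.concatenate(
        [
            np.full(len(to), _TROUGH_SIGMA_FRAC * swing),
            np.full(len(msv), _MSV_SIGMA_FRAC * swing),
            np.full(len(hs), _TROUGH_SIGMA_FRAC * swing),
        ]
    )
    sig = _gauss_lobes(t, centers, amps, sigmas)

    # turn sway: smooth low bump, well below any detection prominence
    in_turn = (t >= turn_start) & (t <= turn_end)
    u = (t[in_turn] - turn_start) / max(turn_end - turn_start, 1e-9)
    sig[in_turn] += _TURN_AMP_FRAC * a * np.sin(np.pi * u) ** 2

    if params.noise_sd > 0:
        sig = sig + rng.normal(0.0, params.noise_sd, n_samp)

    rec = RawRecording(
        subject_id=subject_id, foot=foot, task=task, sampling_rate=fs, samples=sig
    )
    gt = GroundTruth(
        to_s=to,
        msv_s=msv,
        hs_s=hs,
        turn_start_s=float(turn_start),
        turn_end_s=float(turn_end),
        stride_times_s=stride_times,
        velocity_mps=velocity,
    )
    return rec, gt


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskParamDist:
    """Between-subject (mean, SD) distributions of StrideParams for one task."""

    swing_s: tuple[float, float]
    stance_s: tuple[float, float]
    velocity_mps: tuple[float, float]
    jitter_cov: tuple[float, float]
    noise_sd: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        for name in ("swing_s", "stance_s", "velocity_mps", "jitter_cov"):
            m, s = getattr(self, name)
            if s < 0:
                raise InvalidParameterError(f"{name} SD must be >= 0")


@dataclass(frozen=True)
class CovariateDist:
    age_yr: tuple[float, float]
    female_frac: float
    bmi: tuple[float, float]
    education_yr: tuple[float, float]


def default_task_dists() -> dict[str, dict[str, TaskParamDist]]:
    """Group-level gait distributions for the two study groups.

    Controls walk faster with shorter stride times; the T2DM group is slower,
    has longer strides and a noisier signal (driving a higher complexity
    index).  The T2DM normal-walk velocity SD is 0.17 m/s, in line with every
    other velocity SD in the cohort.
    """
    return {
        "control": {
            "normal": TaskParamDist((0.50, 0.04), (0.51, 0.07), (1.35, 0.16), (3.1, 1.2), 0.05),
            "fast": TaskParamDist((0.48, 0.05), (0.42, 0.07), (1.72, 0.19), (4.4, 1.5), 0.05),
            "dual": TaskParamDist((0.54, 0.07), (0.53, 0.10), (1.34, 0.24), (5.2, 1.8), 0.05),
        },
        "t2dm": {
            "normal": TaskParamDist((0.52, 0.05), (0.54, 0.07), (1.12, 0.17), (3.1, 1.2), 0.08),
            "fast": TaskParamDist((0.50, 0.07), (0.44, 0.07), (1.53, 0.27), (4.3, 1.5), 0.08),
            "dual": TaskParamDist((0.55, 0.09), (0.56, 0.10), (1.21, 0.31), (5.8, 2.0), 0.08),
        },
    }


def default_covariate_dists() -> dict[str, CovariateDist]:
    return {
        "control": CovariateDist((51.9, 8.1), 0.43, (26.6, 3.2), (17.7, 2.2)),
        "t2dm": CovariateDist((52.8, 8.3), 0.53, (32.4, 7.8), (17.2, 3.0)),
    }


#: Table-2-style MoCA subdomain (mean, SD, max) per group
_MOCA_DOMAINS = {
    "visuospatial_executive": ({"control": (4.9, 0.29), "t2dm": (4.5, 0.74)}, 5),
    "naming": ({"control": (3.0, 0.05), "t2dm": (3.0, 0.10)}, 3),
    "attention": ({"control": (6.0, 0.05), "t2dm": (5.7, 0.61)}, 6),
    "language": ({"control": (3.0, 0.21), "t2dm": (2.8, 0.49)}, 3),
    "abstraction": ({"control": (2.0, 0.05), "t2dm": (1.9, 0.30)}, 2),
    "delayed_recall": ({"control": (4.2, 0.79), "t2dm": (3.9, 1.21)}, 5),
    "orientation": ({"control": (5.9, 0.25), "t2dm": (5.9, 0.24)}, 6),
}

CANTAB_TASKS = (
    "pal_first_attempt_memory",
    "swm_strategy",
    "prm_percent_correct_delayed",
    "reaction_time_median",
    "ots_first_choice",
    "rvp",
)


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated cohort.

    ``moca_per_mps`` is the linkage coefficient: MoCA points gained per m/s of
    true walking velocity, applied to each of the three tasks.  The default
    calibration (3.0 points per m/s, residual SD 1.5) yields a pooled Pearson
    correlation between normal-walk velocity and MoCA of ~0.4 at n = 138.
    """

    n_control: int = 44
    n_t2dm: int = 94
    fs: float = 200.0
    seed: int = 0
    task_dists: dict = field(default_factory=default_task_dists)
    covariate_dists: dict = field(default_factory=default_covariate_dists)
    moca_intercept: float = 15.9
    moca_per_mps: float = 3.0
    moca_residual_sd: float = 1.5
    foot_velocity_cov: float = 0.02
    turn_s: float = 3.0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_t2dm < 1:
            raise InvalidParameterError("group sizes must be >= 1")
        if self.moca_residual_sd <= 0:
            raise InvalidParameterError("moca_residual_sd must be positive")


def _draw_stride_params(dist: TaskParamDist, rng: np.random.Generator) -> StrideParams:
    draw = lambda ms, lo: max(lo, rng.normal(*ms))
    return StrideParams(
        swing_s=draw(dist.swing_s, 0.2),
        stance_s=draw(dist.stance_s, 0.2),
        velocity_mps=draw(dist.velocity_mps, 0.4),
        amplitude=dist.amplitude,
        noise_sd=dist.noise_sd,
        stride_jitter_cov=draw(dist.jitter_cov, 0.3),
    )


def simulate_cohort(
    config: CohortConfig, signals: bool = True
) -> tuple[pd.DataFrame, dict, dict]:
    """Generate a cohort table plus per-subject/foot/task recordings and truths.

    Returns ``(cohort, recordings, truths)`` where the dicts are keyed by
    ``(subject_id, foot, task)``.  With ``signals=False`` the raw waveforms are
    skipped (recordings dict empty) but ground truths and the cohort table are
    still produced — useful for statistics at scale.

    MoCA is generated as intercept + linkage x (sum of true task velocities)
    + Gaussian residual (+1 point for <= 12 years of education), truncated to
    [0, 30] and rounded last.
    """
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_control + config.n_t2dm
    subj_seeds = root.spawn(n_total)

    rows = []
    recordings: dict = {}
    truths: dict = {}
    groups = ["control"] * config.n_control + ["t2dm"] * config.n_t2dm
    for idx, (group, sseq) in enumerate(zip(groups, subj_seeds)):
        rng = np.random.default_rng(sseq)
        sid = f"S{idx:03d}"
        cov = config.covariate_dists[group]
        age = rng.normal(*cov.age_yr)
        sex = "F" if rng.random() < cov.female_frac else "M"
        bmi = max(16.0, rng.normal(*cov.bmi))
        edu = max(6.0, rng.normal(*cov.education_yr))

        true_vel = {}
        true_params = {}
        for task in TASKS:
            params = _draw_stride_params(config.task_dists[group][task], rng)
            true_vel[task] = params.velocity_mps
            true_params[task] = params
            for foot in FEET:
                fmult = 1.0 + config.foot_velocity_cov * rng.standard_normal()
                fparams = StrideParams(
                    swing_s=params.swing_s,
                    stance_s=params.stance_s,
                    velocity_mps=params.velocity_mps * max(0.5, fmult),
                    amplitude=params.amplitude,
                    noise_sd=params.noise_sd,
                    stride_jitter_cov=params.stride_jitter_cov,
                )
                walk_seed = int(rng.integers(0, 2**31 - 1))
                if signals:
                    rec, gt = simulate_walk(
                        fparams,
                        task=task,
                        fs=config.fs,
                        seed=walk_seed,
                        turn_s=config.turn_s,
                        subject_id=sid,
                        foot=foot,
                    )
                    recordings[(sid, foot, task)] = rec
                    truths[(sid, foot, task)] = gt

        moca_cont = (
            config.moca_intercept
            + config.moca_per_mps * sum(true_vel.values())
            + rng.normal(0.0, config.moca_residual_sd)
        )
        if edu <= 12:
            moca_cont += 1.0
        moca_total = int(round(np.clip(moca_cont, 0.0, 30.0)))

        row = {
            "subject_id": sid,
            "group": group,
            "age_yr": age,
            "sex": sex,
            "bmi": bmi,
            "education_yr": edu,
            "moca_total": moca_total,
        }
        for dom, (bygroup, cap) in _MOCA_DOMAINS.items():
            m, s = bygroup[group]
            row[f"moca_{dom}"] = int(np.clip(round(rng.normal(m, s)), 0, cap))
        vstd = (true_vel["normal"] - 1.2) / 0.2  # weak, sub-threshold coupling
        for ct in CANTAB_TASKS:
            row[f"cantab_{ct}_z"] = 0.15 * vstd + rng.normal(0.0, 1.0)
        for task in TASKS:
            row[f"true_velocity_{task}_mps"] = true_vel[task]
            row[f"true_stride_{task}_s"] = true_params[task].stride_s
            row[f"true_cov_{task}_pct"] = true_params[task].stride_jitter_cov
        rows.append(row)

    cohort = pd.DataFrame(rows)
    return cohort, recordings, truths


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as plain tabular text: time_s, ax, ay, az."""
    path = Path(path)
    x = rec.samples
    if x.ndim == 1:
        block = np.column_stack([rec.times, x, np.zeros_like(x), np.zeros_like(x)])
    else:
        block = np.column_stack([rec.times, x])
    df = pd.DataFrame(block, columns=["time_s", "ax", "ay", "az"])
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Serialize a GroundTruth as JSON (arrays as lists)."""
    path = Path(path)
    d = asdict(gt)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    path.write_text(json.dumps(d, indent=1))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(**d)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path
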