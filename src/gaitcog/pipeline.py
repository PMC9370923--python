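"""End-to-end orchestration: simulate -> preprocess -> events -> temporal
features -> complexity -> screening -> prediction models, as one reproducible
run with a manifest.

Per-stage seeds are derived from the master seed by hashing the stage name
(CRC-32), so adding a stage never perturbs the draws of earlier stages.  Two
runs with the same config and master seed produce byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import entropy, events, models, preprocess, synthetic, temporal
from .cohort import screen_correlations
from .errors import GaitcogError
from .preprocess import RawRecording

log = logging.getLogger("gaitcog")

GAIT_MEASURES = ("velocity_mps", "swing_s", "stance_s", "stride_s", "cov_pct", "complexity")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master combined with CRC-32 of the name."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    out_dir: str = "run"
    input_dir: str | None = None  # if set, load recordings instead of simulating
    n_control: int = 4
    n_t2dm: int = 8
    master_seed: int = 0
    fs: float = 200.0
    trim_start_s: float | None = None
    trim_end_s: float | None = None
    cutoff_hz: float = preprocess.DEFAULT_CUTOFF_HZ
    axis: str | int = "auto"
    min_prominence_frac: float = events.DEFAULT_PROMINENCE_FRAC
    min_separation_s: float = events.DEFAULT_SEPARATION_S
    sampen_m: int = entropy.DEFAULT_M
    sampen_r: float = entropy.DEFAULT_R
    tau_max: int = entropy.DEFAULT_TAU_MAX
    screen_threshold: float = 0.3
    model_repeats: int = 20
    model_split: float = 0.8
    nn_max_epochs: int = 10_000
    nn_patience: int = 50
    write_recordings: bool = False
    velocity_from: str = "recording"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class WalkFeatures:
    summary: temporal.GaitSummary
    events: events.EventSeries
    mse: entropy.MSECurve
    strides: temporal.StrideTable


def extract_features(rec: RawRecording, cfg: RunConfig | None = None) -> WalkFeatures:
    """Run the per-recording chain on one walk.

    Event detection runs on the smoothed signal; the complexity index is
    computed from the trimmed, 200 Hz, unfiltered signal, as in the original
    processing chain.
    """
    cfg = cfg or RunConfig()
    if cfg.trim_start_s is not None or cfg.trim_end_s is not None:
        rec = preprocess.trim(
            rec,
            cfg.trim_start_s or 0.0,
            cfg.trim_end_s if cfg.trim_end_s is not None else rec.duration,
        )
    rec200 = preprocess.resample_to_200hz(rec)
    clean = preprocess.smooth(rec200, cutoff_hz=cfg.cutoff_hz, axis=cfg.axis)
    ev = events.detect_events(
        clean,
        min_prominence_frac=cfg.min_prominence_frac,
        min_separation_s=cfg.min_separation_s,
    )
    tbl = temporal.remove_turn_artifact(temporal.stride_intervals(ev))
    raw_axis = preprocess.select_axis(rec200.samples, cfg.axis)
    curve = entropy.mse_curve(
        raw_axis, entropy.SampEnParams(m=cfg.sampen_m, r=cfg.sampen_r, tau_max=cfg.tau_max)
    )
    summary = temporal.summarize(
        clean, ev, tbl, curve.complexity_index, velocity_from=cfg.velocity_from
    )
    return WalkFeatures(summary=summary, events=ev, mse=curve, strides=tbl)


def summaries_frame(rows: list[temporal.GaitSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in rows])


def gait_feature_frame(summaries: pd.DataFrame) -> pd.DataFrame:
    """One row per subject, columns ``<measure>_<task>_<foot>``."""
    frames = []
    for measure in GAIT_MEASURES:
        wide = summaries.pivot_table(
            index="subject_id", columns=["task", "foot"], values=measure
        )
        name = measure.removesuffix("_mps").removesuffix("_pct").removesuffix("_s")
        wide.columns = [f"{name}_{task}_{foot}" for task, foot in wide.columns]
        frames.append(wide)
    return pd.concat(frames, axis=1).reset_index()


def cognitive_columns(cohort: pd.DataFrame) -> list[str]:
    return [
        c
        for c in cohort.columns
        if c == "moca_total" or c.startswith("moca_") or c.startswith("cantab_")
    ]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "outputs": []}

    # --- stage: simulate or load -----------------------------------------
    if cfg.input_dir is None:
        sim_seed = stage_seed(cfg.master_seed, "simulate")
        cohort, recordings, _truths = synthetic.simulate_cohort(
            synthetic.CohortConfig(
                n_control=cfg.n_control, n_t2dm=cfg.n_t2dm, fs=cfg.fs, seed=sim_seed
            )
        )
        manifest["stages"]["simulate"] = {
            "seed": sim_seed,
            "n_subjects": len(cohort),
            "n_recordings": len(recordings),
        }
    else:
        from .io import load_recording

        in_dir = Path(cfg.input_dir)
        cohort = pd.read_csv(in_dir / "cohort.csv")
        recordings = {}
        for path in sorted(in_dir.glob("recordings/*.csv")):
            try:
                rec = load_recording(path)
            except GaitcogError as exc:
                raise GaitcogError(f"stage load failed for {path.name}: {exc}") from exc
            recordings[(rec.subject_id, rec.foot, rec.task)] = rec
        manifest["stages"]["load"] = {"n_recordings": len(recordings)}

    if cfg.write_recordings:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for (sid, foot, task), rec in sorted(recordings.items()):
            synthetic.write_recording(rec, rec_dir / f"{sid}_{foot}_{task}.csv")

    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    manifest["outputs"].append(cohort_path.name)

    # --- stage: per-recording feature extraction --------------------------
    rows = []
    event_frames = []
    for (sid, foot, task), rec in sorted(recordings.items()):
        try:
            feats = extract_features(rec, cfg)
        except GaitcogError as exc:
            raise GaitcogError(
                f"stage extract failed for {sid}/{foot}/{task}: {exc}"
            ) from exc
        rows.append(feats.summary)
        ef = feats.events.to_frame()
        ef.insert(0, "task", task)
        ef.insert(0, "foot", foot)
        ef.insert(0, "subject_id", sid)
        event_frames.append(ef)
    summaries = summaries_frame(rows)
    summaries.to_csv(out / "summaries.csv", index=False, float_format="%.10g")
    pd.concat(event_frames, ignore_index=True).to_csv(
        out / "events.csv", index=False, float_format="%.10g"
    )
    manifest["outputs"] += ["summaries.csv", "events.csv"]
    manifest["stages"]["extract"] = {"n_summaries": len(rows)}

    # --- stage: screening --------------------------------------------------
    gait_wide = gait_feature_frame(summaries)
    joined = cohort.merge(gait_wide, on="subject_id", how="inner")
    gait_vars = [c for c in gait_wide.columns if c != "subject_id"]
    cog_vars = cognitive_columns(cohort)
    screening = screen_correlations(joined, gait_vars, cog_vars, threshold=cfg.screen_threshold)
    screening.to_csv(out / "screening.csv", index=False, float_format="%.10g")
    manifest["outputs"].append("screening.csv")
    manifest["stages"]["screen"] = {
        "threshold": cfg.screen_threshold,
        "n_selected": int(screening["selected"].sum()),
    }

    # --- stage: prediction models -----------------------------------------
    vel_cols = [c for c in gait_vars if c.startswith("velocity_")]
    X = joined[vel_cols].to_numpy(dtype=float)
    y = joined["moca_total"].to_numpy(dtype=float)
    model_seed = stage_seed(cfg.master_seed, "models")
    rep_mlr = models.validate(
        "mlr", X, y, repeats=cfg.model_repeats, split=cfg.model_split, seed=model_seed
    )
    rep_nn = models.validate(
        "nn",
        X,
        y,
        repeats=cfg.model_repeats,
        split=cfg.model_split,
        seed=model_seed,
        max_epochs=cfg.nn_max_epochs,
        patience=cfg.nn_patience,
    )
    comp = models.compare_models(rep_nn, rep_mlr)
    fit_all = models.fit_mlr(X, y, input_names=tuple(vel_cols))
    report = {
        "inputs": vel_cols,
        "mlr": rep_mlr.to_dict(),
        "nn": rep_nn.to_dict(),
        "comparison": asdict(comp),
        "mlr_full_fit": {
            "coef": fit_all.coef.tolist(),
            "intercept": fit_all.intercept,
            "conf_int": fit_all.conf_int.tolist(),
        },
        "seed": model_seed,
    }
    (out / "validation.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest["outputs"].append("validation.json")
    manifest["stages"]["models"] = {
        "seed": model_seed,
        "mlr_mean_mae": rep_mlr.mean_mae,
        "nn_mean_mae": rep_nn.mean_mae,
        "verdict": comp.verdict,
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %s", out)
    return manifest
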