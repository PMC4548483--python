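"""End-to-end pipeline: simulate -> extract -> normalize -> align ->
analyze -> evaluate, with a run manifest and human-readable tables.

One YAML (or dict) config governs all stages; per-stage seeds are
derived from a single master seed by fixed offsets, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import align
from .features import FrameSpec, extract_features, feature_names
from .modeling import CVProtocol, evaluate_all
from .normalize import ScoreStandardizer, gaussianize_features
from .ppt_analysis import analysis_table
from .synthetic_corpus import build_corpus, load_waveform, read_corpus
from .types import PPT_TESTS, LatentFatigueParams, StudyConfig, VoiceDriftParams

__all__ = ["run_pipeline", "extract_corpus_features", "assemble_dataset"]

_SEED_OFFSETS = {"corpus": 11, "protocol": 23}


def _study_config(cfg: dict[str, Any], seed: int) -> StudyConfig:
    study = dict(cfg.get("study", {}))
    for key in ("slots_per_subject", "baselines_per_subject",
                "post_per_subject", "ppt_sessions_per_subject",
                "duration_bounds_s"):
        if key in study:
            study[key] = tuple(study[key])
    if "isolation_start" in study and isinstance(study["isolation_start"], str):
        study["isolation_start"] = datetime.fromisoformat(study["isolation_start"])
    study.setdefault("rng_seed", (seed + _SEED_OFFSETS["corpus"]) % (2**31))
    return StudyConfig(**study)


def _drift_params(cfg: dict[str, Any]) -> VoiceDriftParams:
    drift = dict(cfg.get("drift", {}))
    if drift.pop("null", False):
        return VoiceDriftParams.null()
    for key in ("formants_hz", "formant_bandwidths_hz"):
        if key in drift:
            drift[key] = tuple(drift[key])
    return VoiceDriftParams(**drift)


def extract_corpus_features(
    corpus_dir: str | Path,
    recordings,
    frame_spec: FrameSpec | None = None,
) -> pd.DataFrame:
    """Extract the 1093-value vector of every recording with audio.

    Returns a DataFrame indexed by recording_id with named feature
    columns; failures carry the recording identity.
    """
    rows = {}
    for rec in recordings:
        if not rec.wav_path:
            continue
        x = load_waveform(corpus_dir, rec)
        try:
            fv = extract_features(x, rec.sample_rate, frame_spec)
        except ValueError as exc:
            raise ValueError(f"feature extraction failed for "
                             f"{rec.recording_id}: {exc}") from exc
        rows[rec.recording_id] = fv.values
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(feature_names()))


def assemble_dataset(
    corpus_dir: str | Path,
    features: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Align a corpus and build the modeling matrices.

    Returns a dict with the gaussianized speech matrix, the latency and
    phase time features, the six targets (latency in minutes, phase as
    minutes of day, four z-standardized PPT scores), subject ids, the
    fitted score standardizer, and the aligned/excluded sample lists.
    """
    corpus_dir = Path(corpus_dir)
    recordings, sessions = read_corpus(corpus_dir)
    if features is None:
        features = extract_corpus_features(corpus_dir, recordings)
    aligned, excluded = align(recordings, sessions)
    aligned = [a for a in aligned if a.recording.recording_id in features.index]

    # gaussianize over every recording of each subject (baselines and
    # post-isolation included): feature normalization precedes alignment
    subj_by_id = {r.recording_id: r.subject_id for r in recordings}
    all_subjects = np.array([subj_by_id[rid] for rid in features.index])
    gauss_all = gaussianize_features(features, all_subjects)

    rec_ids = [a.recording.recording_id for a in aligned]
    subject_ids = np.array([a.recording.subject_id for a in aligned])
    gauss = gauss_all.loc[rec_ids]

    latency_min = np.array([a.latency_min for a in aligned])
    phase_cov = np.array([a.phase for a in aligned])
    phase_min_of_day = np.array([
        (a.recording.start_time.hour * 60 + a.recording.start_time.minute
         + a.recording.start_time.second / 60.0) for a in aligned])

    score_df = pd.DataFrame({
        "subject_id": subject_ids,
        **{t: [a.session.score(t) for a in aligned] for t in PPT_TESTS},
    })
    standardizer = ScoreStandardizer.fit(score_df, tests=PPT_TESTS)
    targets: dict[str, np.ndarray] = {
        "latency_min": latency_min,
        "phase_min": phase_min_of_day,
    }
    for t in PPT_TESTS:
        targets[f"{t}_z"] = standardizer.transform(
            score_df[t].to_numpy(), subject_ids, t)

    return {
        "speech_features": gauss.to_numpy(),
        "time_features": np.column_stack([latency_min, phase_cov]),
        "targets": targets,
        "subject_ids": subject_ids,
        "standardizer": standardizer,
        "raw_scores": score_df,
        "aligned": aligned,
        "excluded": excluded,
    }


def run_pipeline(config: dict[str, Any] | str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline and write tables, metrics, and a manifest.

    Emits, under ``out_dir``: the synthetic corpus, the feature table,
    a mixed-model coefficient table, the cross-validation metric tables
    for the time/latency and PPT experiments (CSV + JSON + Markdown),
    and ``manifest.json`` tying every artifact to the config hash.
    Stage failures abort with the stage name; the manifest then lists
    the outputs completed so far.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest: dict[str, Any] = {
        "config_hash": cfg_hash, "seed": seed,
        "version": __version__, "outputs": {}, "stage_completed": None,
    }

    def _fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        study = _study_config(config, seed)
        fatigue = LatentFatigueParams()
        drift = _drift_params(config)
        corpus_dir = out_dir / "corpus"
        recordings, sessions = build_corpus(study, corpus_dir, fatigue, drift)
        manifest["outputs"]["corpus"] = str(corpus_dir)
        manifest["stage_completed"] = "simulate"
    except Exception as exc:
        _fail("simulate", exc)

    try:
        features = extract_corpus_features(corpus_dir, recordings)
        features.to_csv(out_dir / "features.csv", index_label="recording_id")
        manifest["outputs"]["features"] = str(out_dir / "features.csv")
        manifest["stage_completed"] = "extract"
    except Exception as exc:
        _fail("extract", exc)

    try:
        data = assemble_dataset(corpus_dir, features)
        manifest["n_aligned"] = len(data["aligned"])
        manifest["n_excluded"] = len(data["excluded"])
        manifest["stage_completed"] = "align"
    except Exception as exc:
        _fail("align", exc)

    try:
        ppt_df = pd.DataFrame({
            "subject_id": data["subject_ids"],
            "latency_h": np.array([a.latency_min for a in data["aligned"]]) / 60.0,
            "phase": np.array([a.phase for a in data["aligned"]]),
            **{t: data["raw_scores"][t].to_numpy() for t in PPT_TESTS},
        })
        mixed = analysis_table(ppt_df)
        mixed.to_csv(out_dir / "mixed_model.csv", index=False)
        manifest["outputs"]["mixed_model"] = str(out_dir / "mixed_model.csv")
        manifest["stage_completed"] = "analyze"
    except Exception as exc:
        _fail("analyze", exc)

    try:
        proto_cfg = dict(config.get("protocol", {}))
        proto = CVProtocol(
            repetitions=int(proto_cfg.get("repetitions", 100)),
            folds=int(proto_cfg.get("folds", 10)),
            rng_seed=(seed + _SEED_OFFSETS["protocol"]) % (2**31),
        )
        grid = evaluate_all(data["speech_features"], data["time_features"],
                            data["targets"], proto)
        grid.to_csv(out_dir / "cv_metrics.csv", index=False)
        metrics_json = grid.round(10).to_dict(orient="records")
        (out_dir / "cv_metrics.json").write_text(
            json.dumps(metrics_json, indent=2, sort_keys=True, allow_nan=True))
        (out_dir / "cv_metrics.md").write_text(_markdown_tables(grid))
        manifest["outputs"]["cv_metrics"] = str(out_dir / "cv_metrics.json")
        manifest["stage_completed"] = "evaluate"
    except Exception as exc:
        _fail("evaluate", exc)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _markdown_tables(grid: pd.DataFrame) -> str:
    lines = ["# Cross-validation results", ""]
    for target, block in grid.groupby("target", sort=False):
        lines += [f"## Target: {target}", "",
                  "| Model | R (SD) | MAE (SD) | RAE (SD) |",
                  "|---|---|---|---|"]
        for _, r in block.iterrows():
            lines.append(
                f"| {r['model']} | {r['R']:.2f} ({r['R_sd']:.2f}) "
                f"| {r['MAE']:.2f} ({r['MAE_sd']:.2f}) "
                f"| {r['RAE_pct']:.2f} ({r['RAE_sd']:.2f})% |")
        lines.append("")
    return "\n".join(lines)
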