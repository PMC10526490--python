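"""End-to-end orchestration: simulate/ingest -> featurize -> crossval -> report.

Each stage writes its output under the run directory keyed by the config
hash; a rerun with the same config skips stages whose outputs already exist.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, config_hash
from .deap import read_deap_subject
from .edf import read_edf
from .evaluation import TrainSettings, binarize_ratings, make_folds, train_and_evaluate
from .features import DEFAULT_BANDS, RawRecording, featurize_recording
from .montage import build_electrode_map
from .storage import (
    read_feature_store,
    read_recording_container,
    write_feature_store,
    write_recording,
)
from .synthetic import BAND_POWER_PRESETS, SynthSpec, generate_dataset

__all__ = ["read_recording", "run_pipeline"]

logger = logging.getLogger("eegdcn")


def read_recording(path, format: str = "array-container", **kwargs) -> RawRecording:
    """Load a recording in any of the supported formats."""
    if format == "array-container":
        return read_recording_container(path)
    if format == "edf":
        return read_edf(path)
    if format == "deap-adapter":
        return read_deap_subject(path, **kwargs)
    raise ValueError(f"unknown recording format {format!r}")


def _labelled(rec: RawRecording) -> RawRecording:
    """Ensure categorical labels exist, binarizing ratings if needed."""
    if rec.labels is None:
        if rec.ratings is None:
            raise ValueError(f"recording for subject {rec.subject_id} has neither labels nor ratings")
        from dataclasses import replace

        return replace(rec, labels=binarize_ratings(rec.ratings))
    return rec


def _stage(name: str, path: Path, build, verbosity: int):
    if path.exists():
        logger.info("stage %s: cached at %s", name, path)
        return
    t0 = time.perf_counter()
    try:
        build()
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: %.2fs -> %s", name, time.perf_counter() - t0, path)


def run_pipeline(cfg: RunConfig) -> dict:
    chash = config_hash(cfg)
    workdir = Path(cfg.workdir) / chash
    workdir.mkdir(parents=True, exist_ok=True)
    cfg.save(workdir / "config.yaml")
    logging.basicConfig(level=logging.INFO if cfg.verbosity else logging.WARNING)

    # ---------------------------------------------------------------- ingest
    rec_paths: list[Path]
    if cfg.recording_path is not None:
        rec_paths = [Path(cfg.recording_path)]
        recordings = [_labelled(read_recording(cfg.recording_path, cfg.recording_format))]
    else:
        spec = SynthSpec(
            n_subjects=cfg.n_subjects,
            n_trials_per_subject=cfg.n_trials_per_subject,
            n_channels=cfg.n_channels,
            sampling_rate=cfg.sampling_rate,
            trial_seconds=cfg.trial_seconds,
            baseline_seconds=cfg.baseline_seconds,
            class_scheme=cfg.class_scheme,
            band_power_map=BAND_POWER_PRESETS[cfg.band_power_preset],
            noise_sd=cfg.noise_sd,
            seed=cfg.seed,
        )
        rec_paths = [workdir / f"subject{s:02d}.eegarc" for s in range(cfg.n_subjects)]

        recordings = None

        def simulate():
            nonlocal recordings
            recordings = generate_dataset(spec)
            for p, r in zip(rec_paths, recordings):
                write_recording(p, r)

        _stage("simulate", rec_paths[-1], simulate, cfg.verbosity)
        if recordings is None:
            recordings = [read_recording_container(p) for p in rec_paths]
        recordings = [_labelled(r) for r in recordings]

    # ------------------------------------------------------------- featurize
    feat_path = workdir / "features.eegarc"

    def featurize():
        emap = build_electrode_map(recordings[0].channel_names, cfg.layout)
        all_t, all_y, all_s, all_tr = [], [], [], []
        for rec in recordings:
            t, y, s, tr = featurize_recording(rec, emap, cfg.window_seconds, cfg.step_seconds)
            all_t.append(t)
            all_y.append(y)
            all_s.append(s)
            all_tr.append(tr)
        write_feature_store(
            feat_path,
            np.concatenate(all_t),
            emap.occupancy(),
            np.concatenate(all_y),
            np.concatenate(all_s),
            np.concatenate(all_tr),
            [b.name for b in DEFAULT_BANDS],
            emap.name,
            emap.version,
        )

    _stage("featurize", feat_path, featurize, cfg.verbosity)
    arrays, feat_meta = read_feature_store(feat_path)

    # -------------------------------------------------------------- crossval
    results_path = workdir / "results.json"
    if results_path.exists():
        logger.info("stage crossval: cached at %s", results_path)
        return json.loads(results_path.read_text())

    labels = arrays["labels"]
    subjects = arrays["subject_ids"]
    n_classes = int(labels.max()) + 1
    plan = make_folds(labels, subjects, scheme=cfg.scheme, k=cfg.k, seed=cfg.seed)
    model_cfg = cfg.model_config(n_classes)
    settings = TrainSettings(epochs=cfg.epochs, batch_size=cfg.batch_size, learning_rate=cfg.learning_rate)

    def crossval():
        summary = train_and_evaluate(arrays["tensors"], labels, model_cfg, plan, settings)
        summary["config_hash"] = chash
        summary["package_version"] = __version__
        summary["feature_meta"] = feat_meta
        results_path.write_text(json.dumps(summary, indent=2))

    _stage("crossval", results_path, crossval, cfg.verbosity)
    return json.loads(results_path.read_text())
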