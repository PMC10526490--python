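"""Adapter for DEAP-style preprocessed per-subject files.

Expects a Python pickle holding a dict with ``data`` of shape
(40 trials, 40 channels, 8064 samples) — EEG in the first 32 channels,
peripheral signals after — and ``labels`` of shape (40, 4) with columns
(valence, arousal, dominance, liking) on the 1-9 scale. Only the 32 EEG
channels and the requested rating dimension are kept.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from .features import RawRecording
from .montage import DEAP_CHANNELS

__all__ = ["read_deap_subject", "N_EEG_CHANNELS", "SAMPLING_RATE", "BASELINE_SECONDS"]

N_EEG_CHANNELS = 32
SAMPLING_RATE = 128.0
BASELINE_SECONDS = 3.0
_DIMENSIONS = {"valence": 0, "arousal": 1}


def read_deap_subject(path, dimension: str = "valence", subject_id: int = 0) -> RawRecording:
    path = Path(path)
    if dimension not in _DIMENSIONS:
        raise ValueError(f"dimension must be one of {sorted(_DIMENSIONS)}, got {dimension!r}")
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
    except (pickle.UnpicklingError, EOFError) as exc:
        raise ValueError(f"malformed subject file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "data" not in payload or "labels" not in payload:
        raise ValueError(f"subject file {path} must be a dict with 'data' and 'labels'")
    data = np.asarray(payload["data"], dtype=np.float64)
    ratings = np.asarray(payload["labels"], dtype=np.float64)
    if data.ndim != 3 or data.shape[1] < N_EEG_CHANNELS:
        raise ValueError(f"expected (trials, >= {N_EEG_CHANNELS} channels, samples), got {data.shape}")
    if ratings.shape[0] != data.shape[0]:
        raise ValueError("labels must have one row per trial")
    return RawRecording(
        data=data[:, :N_EEG_CHANNELS, :],
        sampling_rate=SAMPLING_RATE,
        channel_names=DEAP_CHANNELS,
        baseline_seconds=BASELINE_SECONDS,
        ratings=ratings[:, _DIMENSIONS[dimension]],
        subject_id=subject_id,
    )
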