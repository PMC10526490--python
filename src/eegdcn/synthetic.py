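"""Synthetic EEG with known class structure.

Each trial is a sum of four band-limited components (white Gaussian noise
pushed through the same zero-phase Butterworth band-pass filters the feature
pipeline uses, then rescaled so the in-band standard deviation matches the
class's entry in ``band_power_map``) plus broadband Gaussian noise. Labels
attach to trials; segment labels are inherited downstream. Not intended to
be physiologically realistic — no 1/f background, no artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import sosfiltfilt

from .features import DEFAULT_BANDS, BandDefinition, RawRecording
from .montage import DEAP_CHANNELS

__all__ = ["SynthSpec", "generate_recording", "generate_dataset", "BAND_POWER_PRESETS"]

#: per-class (theta, alpha, beta, gamma) signal standard deviations
BAND_POWER_PRESETS: dict[str, list[list[float]]] = {
    # well-separated classes: low vs high-frequency dominance
    "easy-binary": [[2.0, 1.2, 0.3, 0.2], [0.3, 0.2, 1.6, 2.0]],
    "medium-binary": [[1.0, 0.8, 0.5, 0.4], [0.5, 0.4, 0.8, 1.0]],
    "hard-binary": [[0.7, 0.6, 0.55, 0.5], [0.55, 0.5, 0.7, 0.6]],
    "easy-ternary": [[2.0, 1.0, 0.3, 0.2], [0.5, 2.0, 0.5, 0.4], [0.3, 0.2, 1.5, 2.0]],
}


@dataclass
class SynthSpec:
    """Parameters of the synthetic-EEG generator."""

    n_subjects: int = 1
    n_trials_per_subject: int = 40
    n_channels: int = 32
    sampling_rate: float = 128.0
    trial_seconds: float = 63.0
    baseline_seconds: float = 3.0
    class_scheme: str = "binary"  # or "ternary"
    band_power_map: list[list[float]] | None = None  # per-class per-band signal sd
    noise_sd: float = 0.5
    seed: int = 0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS

    def __post_init__(self):
        for name in ("n_subjects", "n_trials_per_subject", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.trial_seconds <= self.baseline_seconds:
            raise ValueError("trial_seconds must exceed baseline_seconds")
        highest_edge = max(b.high_hz for b in self.bands)
        if self.sampling_rate <= 2 * highest_edge:
            raise ValueError(
                f"sampling_rate must exceed twice the highest band edge "
                f"({2 * highest_edge} Hz), got {self.sampling_rate}"
            )
        if self.class_scheme not in ("binary", "ternary"):
            raise ValueError(f"class_scheme must be 'binary' or 'ternary', got {self.class_scheme!r}")
        if self.band_power_map is None:
            self.band_power_map = BAND_POWER_PRESETS[f"easy-{self.class_scheme}"]
        self.band_power_map = [[float(v) for v in row] for row in self.band_power_map]
        if len(self.band_power_map) != self.n_classes:
            raise ValueError(
                f"band_power_map must have {self.n_classes} rows for scheme "
                f"{self.class_scheme!r}, got {len(self.band_power_map)}"
            )
        for row in self.band_power_map:
            if len(row) != len(self.bands):
                raise ValueError(f"band_power_map rows must have {len(self.bands)} entries")
            if any(v < 0 for v in row):
                raise ValueError("band_power_map entries must be non-negative")
        distinct = {tuple(row) for row in self.band_power_map}
        if len(distinct) != len(self.band_power_map):
            # classes are then indistinguishable by construction; permitted for
            # degenerate/diagnostic settings but flagged loudly
            warnings.warn(
                "band_power_map rows coincide between classes; generated classes "
                "will be indistinguishable",
                stacklevel=2,
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_classes(self) -> int:
        return 2 if self.class_scheme == "binary" else 3

    @property
    def samples_per_trial(self) -> int:
        n = self.trial_seconds * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_seconds * sampling_rate must be an integer sample count")
        return round(n)


def _trial_labels(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Near-balanced labels: cycle through classes, then shuffle."""
    labels = np.arange(spec.n_trials_per_subject) % spec.n_classes
    rng.shuffle(labels)
    return labels


def _ratings_for_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Synthetic 1-9 ratings consistent with binary labels (threshold 5)."""
    low = rng.uniform(1.0, 4.5, labels.shape)
    high = rng.uniform(5.5, 9.0, labels.shape)
    return np.where(labels == 1, high, low)


def generate_recording(spec: SynthSpec, subject_id: int = 0) -> RawRecording:
    """Generate one subject's recording; bit-reproducible from (seed, subject_id)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_id,)))
    n = spec.samples_per_trial
    labels = _trial_labels(spec, rng)
    sos_per_band = [b.sos(spec.sampling_rate) for b in spec.bands]

    data = np.zeros((spec.n_trials_per_subject, spec.n_channels, n), dtype=np.float64)
    for t, cls in enumerate(labels):
        trial = np.zeros((spec.n_channels, n))
        for b, sos in enumerate(sos_per_band):
            target_sd = spec.band_power_map[cls][b]
            if target_sd == 0:
                continue
            component = sosfiltfilt(sos, rng.standard_normal((spec.n_channels, n)), axis=-1)
            sd = component.std(axis=-1, keepdims=True)
            sd[sd == 0] = 1.0
            trial += component * (target_sd / sd)
        if spec.noise_sd > 0:
            trial += spec.noise_sd * rng.standard_normal((spec.n_channels, n))
        data[t] = trial

    channel_names = (
        DEAP_CHANNELS[: spec.n_channels]
        if spec.n_channels <= len(DEAP_CHANNELS)
        else tuple(f"ch{i}" for i in range(spec.n_channels))
    )
    ratings = _ratings_for_labels(labels, rng) if spec.class_scheme == "binary" else None
    return RawRecording(
        data=data.astype(np.float32),
        sampling_rate=spec.sampling_rate,
        channel_names=channel_names,
        baseline_seconds=spec.baseline_seconds,
        ratings=ratings,
        labels=labels.astype(np.int64),
        subject_id=subject_id,
    )


def generate_dataset(spec: SynthSpec) -> list[RawRecording]:
    """One recording per subject."""
    return [generate_recording(spec, subject_id=s) for s in range(spec.n_subjects)]
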