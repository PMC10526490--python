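"""From raw multi-channel EEG to per-segment differential-entropy grids.

Pipeline: drop the pre-stimulus baseline, cut trials into fixed windows,
band-limit each window with zero-phase Butterworth filters (theta, alpha,
beta, gamma by default), take the Gaussian closed-form differential entropy
of every channel x band, and scatter the values onto the electrode grid to
form an h x w x bands feature tensor per segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .montage import ElectrodeMap

__all__ = [
    "RawRecording",
    "Segment",
    "BandDefinition",
    "DEFAULT_BANDS",
    "DESegment",
    "DEFeatureTensor",
    "strip_baseline",
    "segment_trials",
    "bandpass_decompose",
    "differential_entropy",
    "de_segment",
    "assemble_feature_tensor",
    "featurize_recording",
]


@dataclass
class RawRecording:
    """Per-subject EEG: (trials, channels, samples) plus labelling metadata.

    ``ratings`` holds continuous 1-9 scores (one per trial) for rating-style
    labels, or ``None``; ``labels`` holds categorical class ids per trial, or
    ``None`` (at least one of the two must be present for supervised use).
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    baseline_seconds: float = 0.0
    ratings: np.ndarray | None = None
    labels: np.ndarray | None = None
    subject_id: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (trials, channels, samples), got ndim={self.data.ndim}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        if self.data.shape[2] < self.baseline_seconds * self.sampling_rate:
            raise ValueError("trials shorter than the declared baseline")
        for name in ("ratings", "labels"):
            value = getattr(self, name)
            if value is not None:
                value = np.asarray(value)
                if value.shape[0] != self.data.shape[0]:
                    raise ValueError(f"{name} must have one entry per trial")
                setattr(self, name, value)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def trial_labels(self) -> np.ndarray:
        if self.labels is not None:
            return np.asarray(self.labels, dtype=np.int64)
        raise ValueError("recording carries no categorical labels; binarize ratings first")


@dataclass(frozen=True)
class Segment:
    """One window of one trial, inheriting the trial's label."""

    data: np.ndarray  # (channels, window_samples)
    label: int
    subject_id: int
    trial_id: int
    segment_index: int
    sampling_rate: float


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float
    filter_order: int = 4

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: need 0 < low < high, got ({self.low_hz}, {self.high_hz})")

    def validate_for_rate(self, sampling_rate: float) -> None:
        if self.high_hz >= sampling_rate / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high_hz} Hz at or above Nyquist "
                f"({sampling_rate / 2} Hz)"
            )

    def sos(self, sampling_rate: float):
        self.validate_for_rate(sampling_rate)
        return butter(
            self.filter_order, [self.low_hz, self.high_hz], btype="bandpass", fs=sampling_rate, output="sos"
        )


DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 31.0),
    BandDefinition("gamma", 31.0, 45.0),
)


@dataclass(frozen=True)
class DESegment:
    """Per-channel, per-band differential-entropy values for one segment."""

    values: np.ndarray  # (channels, bands)
    channel_names: tuple[str, ...]
    band_names: tuple[str, ...]
    label: int
    subject_id: int
    trial_id: int
    segment_index: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("differential-entropy values must be finite")


@dataclass(frozen=True)
class DEFeatureTensor:
    """(h, w, bands) grid of DE values with an occupancy mask; unoccupied
    cells are structural zeros."""

    grid: np.ndarray
    mask: np.ndarray
    label: int
    subject_id: int
    trial_id: int
    segment_index: int

    def __post_init__(self):
        if self.grid.shape[:2] != self.mask.shape:
            raise ValueError("grid and mask spatial dims differ")
        if np.any(self.grid[~self.mask] != 0):
            raise ValueError("unoccupied cells must be zero")


# --------------------------------------------------------------------------


def strip_baseline(rec: RawRecording, min_remaining_seconds: float = 1.0) -> RawRecording:
    """Drop the leading ``baseline_seconds`` from every trial (discard only,
    no subtraction). With a zero baseline this is the identity."""
    n_base = round(rec.baseline_seconds * rec.sampling_rate)
    if n_base == 0:
        return rec
    remaining = rec.n_samples - n_base
    if remaining < min_remaining_seconds * rec.sampling_rate:
        raise ValueError(
            f"trials of {rec.n_samples / rec.sampling_rate:g} s are too short for a "
            f"{rec.baseline_seconds:g} s baseline plus {min_remaining_seconds:g} s of signal"
        )
    return replace(rec, data=rec.data[:, :, n_base:], baseline_seconds=0.0)


def segment_trials(rec: RawRecording, window_s: float = 1.0, step_s: float = 1.0) -> list[Segment]:
    """Cut every trial into windows of ``window_s`` advanced by ``step_s``.

    Per trial the count is ``floor((trial_s - window_s) / step_s) + 1``; with
    step == window the windows tile the trial without overlap. Each segment
    inherits its trial's label.
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be positive")
    window = window_s * rec.sampling_rate
    step = step_s * rec.sampling_rate
    if abs(window - round(window)) > 1e-9 or abs(step - round(step)) > 1e-9:
        raise ValueError(
            f"window ({window_s} s) and step ({step_s} s) must be whole numbers of samples "
            f"at {rec.sampling_rate} Hz"
        )
    window, step = round(window), round(step)
    if window > rec.n_samples:
        raise ValueError(f"window of {window} samples exceeds trial length {rec.n_samples}")
    labels = rec.trial_labels() if (rec.labels is not None) else np.zeros(rec.n_trials, dtype=np.int64)
    segments: list[Segment] = []
    n_per_trial = (rec.n_samples - window) // step + 1
    for t in range(rec.n_trials):
        for k in range(n_per_trial):
            start = k * step
            segments.append(
                Segment(
                    data=rec.data[t, :, start : start + window],
                    label=int(labels[t]),
                    subject_id=rec.subject_id,
                    trial_id=t,
                    segment_index=k,
                    sampling_rate=rec.sampling_rate,
                )
            )
    return segments


def bandpass_decompose(seg: Segment, bands=DEFAULT_BANDS) -> list[Segment]:
    """Zero-phase Butterworth band-pass copies of a segment, one per band."""
    out = []
    for band in bands:
        sos = band.sos(seg.sampling_rate)
        filtered = sosfiltfilt(sos, seg.data, axis=-1)
        out.append(replace_segment_data(seg, filtered))
    return out


def replace_segment_data(seg: Segment, data: np.ndarray) -> Segment:
    return Segment(
        data=data,
        label=seg.label,
        subject_id=seg.subject_id,
        trial_id=seg.trial_id,
        segment_index=seg.segment_index,
        sampling_rate=seg.sampling_rate,
    )


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian closed-form differential entropy of a 1D window, in nats.

    ``0.5 * ln(2 * pi * e * var(x))`` with the plug-in sample variance. A
    constant (zero-variance) window is rejected rather than mapped to -inf.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("differential entropy needs at least 2 samples")
    var = x.var()
    if var <= 0:
        raise ValueError("zero-variance (constant) signal has no finite differential entropy")
    return 0.5 * math.log(2.0 * math.pi * math.e * var)


def de_segment(seg: Segment, bands=DEFAULT_BANDS, channel_names=None) -> DESegment:
    """Band-decompose a segment and take per-channel differential entropy."""
    band_segments = bandpass_decompose(seg, bands)
    values = np.empty((seg.data.shape[0], len(bands)))
    for b, bs in enumerate(band_segments):
        for ch in range(bs.data.shape[0]):
            values[ch, b] = differential_entropy(bs.data[ch])
    return DESegment(
        values=values,
        channel_names=tuple(channel_names) if channel_names is not None else tuple(
            f"ch{i}" for i in range(seg.data.shape[0])
        ),
        band_names=tuple(b.name for b in bands),
        label=seg.label,
        subject_id=seg.subject_id,
        trial_id=seg.trial_id,
        segment_index=seg.segment_index,
    )


def assemble_feature_tensor(de: DESegment, emap: ElectrodeMap) -> DEFeatureTensor:
    """Scatter per-channel DE values onto the electrode grid."""
    n_bands = de.values.shape[1]
    grid = np.zeros((emap.h, emap.w, n_bands))
    mask = np.zeros((emap.h, emap.w), dtype=bool)
    for i, name in enumerate(de.channel_names):
        if name not in emap:
            raise ValueError(f"channel {name!r} is missing from the electrode map")
        r, c = emap[name]
        grid[r, c, :] = de.values[i]
        mask[r, c] = True
    return DEFeatureTensor(
        grid=grid,
        mask=mask,
        label=de.label,
        subject_id=de.subject_id,
        trial_id=de.trial_id,
        segment_index=de.segment_index,
    )


def featurize_recording(
    rec: RawRecording,
    emap: ElectrodeMap,
    window_s: float = 1.0,
    step_s: float = 1.0,
    bands=DEFAULT_BANDS,
):
    """Full feature pipeline for one recording: strip baseline, window, filter
    each window per band, take per-channel DE, scatter onto the grid.

    Returns ``(tensors, labels, subject_ids, trial_ids)`` where ``tensors``
    is an (n_segments, h, w, n_bands) array.
    """
    rec = strip_baseline(rec)
    for band in bands:
        band.validate_for_rate(rec.sampling_rate)
    segments = segment_trials(rec, window_s, step_s)
    rows = np.array([emap[name][0] for name in rec.channel_names])
    cols = np.array([emap[name][1] for name in rec.channel_names])
    sos_per_band = [band.sos(rec.sampling_rate) for band in bands]

    tensors = np.zeros((len(segments), emap.h, emap.w, len(bands)))
    labels = np.empty(len(segments), dtype=np.int64)
    subject_ids = np.full(len(segments), rec.subject_id, dtype=np.int64)
    trial_ids = np.empty(len(segments), dtype=np.int64)
    for i, seg in enumerate(segments):
        for b, sos in enumerate(sos_per_band):
            filtered = sosfiltfilt(sos, np.asarray(seg.data, dtype=np.float64), axis=-1)
            var = filtered.var(axis=-1)
            if np.any(var <= 0):
                raise ValueError(
                    f"zero-variance window in trial {seg.trial_id}, segment {seg.segment_index}"
                )
            tensors[i, rows, cols, b] = 0.5 * np.log(2.0 * math.pi * math.e * var)
        labels[i] = seg.label
        trial_ids[i] = seg.trial_id
    return tensors, labels, subject_ids, trial_ids
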