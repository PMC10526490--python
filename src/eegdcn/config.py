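"""Run configuration: a fully serializable description of an end-to-end run.

A run is reconstructible from its persisted YAML alone; the canonical
serialization (sorted keys) is hashed and embedded into every results file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .nn.model import ModelConfig

__all__ = ["RunConfig", "config_hash"]


@dataclass
class RunConfig:
    # paths
    workdir: str = "runs"
    recording_path: str | None = None  # ingest instead of simulating when set
    recording_format: str = "array-container"  # or "edf" | "deap-adapter"
    # synthetic generator
    n_subjects: int = 2
    n_trials_per_subject: int = 12
    n_channels: int = 32
    sampling_rate: float = 128.0
    trial_seconds: float = 13.0
    baseline_seconds: float = 3.0
    class_scheme: str = "binary"
    band_power_preset: str = "easy-binary"
    noise_sd: float = 0.5
    # preprocessing
    window_seconds: float = 1.0
    step_seconds: float = 1.0
    layout: str = "deap9x9"
    # model + training
    model: dict = field(default_factory=dict)  # overrides for ModelConfig fields
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    # evaluation
    scheme: str = "kfold"
    k: int = 5
    # misc
    seed: int = 0
    verbosity: int = 1

    def model_config(self, n_classes: int) -> ModelConfig:
        overrides = dict(self.model)
        overrides.setdefault("n_classes", n_classes)
        overrides.setdefault("seed", self.seed)
        return ModelConfig(**overrides)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.to_yaml().encode()).hexdigest()[:16]
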