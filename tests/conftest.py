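import numpy as np
import pytest

from eegdcn.features import featurize_recording
from eegdcn.montage import build_electrode_map
from eegdcn.nn import ModelConfig
from eegdcn.synthetic import SynthSpec, generate_dataset, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_recording():
    """4 trials x 32 channels x 7 s at 128 Hz (3 s baseline)."""
    spec = SynthSpec(n_trials_per_subject=4, trial_seconds=7.0, seed=11)
    return generate_recording(spec)


def small_model_config(**overrides) -> ModelConfig:
    base = dict(stage_widths=(8, 16, 32, 32), lateral_channels=16, gru_hidden=8, seed=0)
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def small_config():
    return small_model_config()


@pytest.fixture(scope="session")
def easy_features():
    """DE features for the well-separated binary generator setting.

    2 subjects x 12 trials x 10 s stimulus -> 240 segments of 9x9x4.
    """
    spec = SynthSpec(n_subjects=2, n_trials_per_subject=12, trial_seconds=13.0, seed=7)
    recordings = generate_dataset(spec)
    emap = build_electrode_map(recordings[0].channel_names)
    parts = [featurize_recording(rec, emap) for rec in recordings]
    x = np.concatenate([p[0] for p in parts])
    y = np.concatenate([p[1] for p in parts])
    subjects = np.concatenate([p[2] for p in parts])
    return x, y, subjects
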