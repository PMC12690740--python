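import numpy as np
import pytest

from buzzscan.annotations import MatchPolicy
from buzzscan.audio_io import AudioClip, FrameSpec
from buzzscan.features import get_provider


@pytest.fixture(scope="session")
def provider():
    return get_provider()


@pytest.fixture(scope="session")
def frame_spec():
    return FrameSpec()


@pytest.fixture(scope="session")
def policy():
    return MatchPolicy()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def sine_clip(freq_hz: float, duration_s: float, sample_rate: int, amplitude: float = 0.5) -> AudioClip:
    t = np.arange(round(duration_s * sample_rate)) / sample_rate
    return AudioClip(samples=amplitude * np.sin(2 * np.pi * freq_hz * t), sample_rate=sample_rate)


@pytest.fixture(scope="session")
def trained_tiny_experiment():
    """One small end-to-end run shared by the integration-level tests."""
    from buzzscan.pipeline import run_experiment

    return run_experiment(seed=11, n_train=8, n_cal=5, n_test=5, scene_duration_s=120.0)
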