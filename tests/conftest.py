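import numpy as np
import pytest

from nasometry import (
    DualChannelRecording,
    FrameConfig,
    GateConfig,
    NasalanceTrajectory,
    design_bandpass,
)

SR = 44_100


@pytest.fixture
def default_filter():
    return design_bandpass(200, 800, order=2, sample_rate=SR)


@pytest.fixture
def frame_config():
    return FrameConfig(window_s=0.050, overlap_fraction=0.5)


@pytest.fixture
def gate_off():
    return GateConfig(enabled=False)


def make_recording(nasal, oral, sample_rate=SR):
    return DualChannelRecording(nasal=np.asarray(nasal, float),
                                oral=np.asarray(oral, float),
                                sample_rate=sample_rate)


def make_trajectory(values, hop_s=0.025, valid=None):
    """Build a bare trajectory from nasalance values for agreement tests."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    times = 0.025 + hop_s * np.arange(values.size)
    return NasalanceTrajectory(
        times_s=times, nasalance_pct=values, valid=np.asarray(valid, bool),
        nasal_rms=np.zeros(values.size), oral_rms=np.zeros(values.size),
        hop_s=hop_s,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
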