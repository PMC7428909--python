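import numpy as np
import pytest

from ppgresp import (SimulationConfig, simulate_recording,
                     build_feature_windows)
from ppgresp.preprocessing import FEATURE_RATE_HZ, resample_channel


@pytest.fixture(scope="session")
def am_recording():
    """Clean AM-modulated serial: HR 72, BR 10, depth 0.3, no noise."""
    cfg = SimulationConfig(duration_s=120, breathing_rate_bpm=10,
                           heart_rate_bpm=72, am_depth=0.3, bw_amplitude=0.0,
                           fm_depth=0.0, noise_sd=0.0, seed=5)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def am_ppg25(am_recording):
    return resample_channel(am_recording.ppg, FEATURE_RATE_HZ)


@pytest.fixture(scope="session")
def am_rtv25(am_recording):
    return resample_channel(am_recording.rtv, FEATURE_RATE_HZ)


@pytest.fixture(scope="session")
def small_windows():
    """A handful of real feature windows from one modulated serial."""
    cfg = SimulationConfig(duration_s=300, breathing_rate_bpm=10,
                           am_depth=0.25, bw_amplitude=0.2, fm_depth=0.05,
                           noise_sd=0.05, seed=7)
    return build_feature_windows(simulate_recording(cfg))
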