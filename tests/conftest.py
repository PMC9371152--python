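import dataclasses

import numpy as np
import pytest

from lasersprint import (
    AnalysisConfig,
    GaitConfig,
    MeasurementMeta,
    SimConfig,
    StartEndConfig,
)


@pytest.fixture
def clean_sim_config():
    """Noise-free default sprint."""
    return SimConfig(noise_sd=0.0, seed=1)


@pytest.fixture
def noisy_sim_config():
    """Default sprint with device-class sensor noise."""
    return SimConfig(noise_sd=0.020, seed=1)


@pytest.fixture
def full_run_analysis_config():
    """Pipeline config analysing the full 100 m (end rule at 100 m)."""
    cfg = AnalysisConfig()
    cfg.start_end = dataclasses.replace(cfg.start_end, end_distance=100.0)
    return cfg


@pytest.fixture
def noisy_gait_config():
    """Detection settings recommended for noisy field traces."""
    return GaitConfig(
        detection_smoothing=9,
        detection_passes=3,
        periodic_prune=True,
        refine_halfwidth=5,
    )


@pytest.fixture
def sim_meta():
    return MeasurementMeta(calibration_distance_L1=7.3, first_leg_on_start="L")


def make_uniform_time(n: int, rate: float = 100.0) -> np.ndarray:
    return np.arange(n) / rate
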