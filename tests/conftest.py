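import numpy as np
import pytest

from freegait import PipelineConfig, SimParams, simulate_recording, simulate_walk


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def level_params():
    """Noise-free level walking at the level-asphalt step time."""
    return SimParams(
        duration_s=30.0,
        step_time_mean_l=0.524,
        step_time_mean_r=0.524,
        step_time_sd=0.0,
        noise_sd=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def level_walk(level_params):
    return simulate_walk(level_params)


@pytest.fixture(scope="session")
def padded_walk(level_params):
    """Noise-free 30 s walk flanked by standing, with truth and context."""
    return simulate_recording(
        [("stand", 5), ("walk", 30), ("stand", 5)], level_params
    )
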