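import numpy as np
import pytest

from tugkit import SimulationParams, simulate_tug


@pytest.fixture(scope="session")
def clean_trial():
    """One noise-free simulated TUG trial (radar, insole, truth)."""
    params = SimulationParams(
        seed=42, radar_noise_sd_m=0.0, ay_noise_sd=0.0, force_noise_sd=0.0
    )
    return simulate_tug(params)


@pytest.fixture(scope="session")
def noisy_trial():
    """One TUG trial at the default (realistic) noise levels."""
    return simulate_tug(SimulationParams(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
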