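import warnings

import numpy as np
import pytest

from lagwave import SimulationConfig, simulate_dataset

# run-duration warnings are expected at desk-scale run lengths
warnings.filterwarnings("ignore", message="Run duration")


@pytest.fixture(scope="session")
def small_sim():
    """Compact noiseless single-wave dataset for exact-recovery checks."""
    cfg = SimulationConfig(shape=(12, 12, 4), timepoints_per_run=300, n_runs=2,
                           n_global=1, n_local=0, noise_sd=0.0, seed=5,
                           wave_specs=None)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_noisy_sim():
    """Compact mixed dataset (1 wave + 2 local nets + noise)."""
    cfg = SimulationConfig(shape=(12, 12, 4), timepoints_per_run=300, n_runs=2,
                           n_global=1, n_local=2, noise_sd=0.3, seed=6)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """One instance of the default study configuration."""
    return simulate_dataset(SimulationConfig(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
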