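import numpy as np
import pytest

from emg2pen import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2 synthetic subjects x 10 digits x 8 trials, default rates and SNR."""
    cfg = SimulationConfig(n_subjects=2, n_trials_per_symbol=8, seed=42)
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_dataset():
    """1 subject x 3 digits x 4 trials — smallest scale that still splits."""
    cfg = SimulationConfig(
        n_subjects=1, n_trials_per_symbol=4, symbols=(0, 1, 2), seed=7
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
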