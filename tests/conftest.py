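import numpy as np
import pytest

from introntrace.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared (read-only) across tests."""
    return simulate_study(SimulationConfig(seed=11, n_genes=6))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_genes=6)
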