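import numpy as np
import pytest

from tumorgame import SimulationConfig, run_simulation, initialize_world, step_world


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """Small, fast, valid configuration for unit tests."""
    return SimulationConfig(L=21, t_max=10, seed=5)


@pytest.fixture(scope="session")
def smoke_result():
    """One full smoke-scale simulation, shared across tests that only read it."""
    return run_simulation(SimulationConfig(L=61, t_max=30, seed=11))


@pytest.fixture(scope="session")
def step_sequence():
    """A trajectory of consecutive states from a small lattice, for invariants."""
    config = SimulationConfig(L=41, t_max=20, seed=17)
    rng = np.random.default_rng(config.seed)
    state = initialize_world(config, rng)
    states = [state]
    for _ in range(config.t_max):
        state = step_world(state, config, rng)
        states.append(state)
    return config, states
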