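import numpy as np
import pytest

from cardioresp import SimulationConfig, generate_cohort, simulate_record


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_record(default_config):
    """One deterministic three-epoch record shared across tests."""
    record, truth = simulate_record(default_config)
    return record, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Ten default subjects, enough for paired statistics."""
    return generate_cohort(10, SimulationConfig(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
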