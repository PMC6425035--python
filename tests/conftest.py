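import pytest

from epispread.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One default synthetic study shared by every test that reads it."""
    return simulate_dataset(default_config)
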