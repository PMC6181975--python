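import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ste3c import digest, simulate_locus
from ste3c.config import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_locus(default_config):
    """One default synthetic locus shared across tests: (sequence, truth, fragments)."""
    sequence, truth = simulate_locus(default_config)
    frags = digest(sequence, default_config.motif, default_config.cut_offset,
                   default_config.chrom)
    return sequence, truth, frags


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
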