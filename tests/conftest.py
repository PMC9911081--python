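import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: The spliced leader used as a realistic fixture throughout the suite.
SL32 = "GCCTAATTGTTGTGATAAACTTATTAAATAGA"


@pytest.fixture
def sl32() -> str:
    return SL32


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def default_dataset():
    """One default simulated dataset, shared across tests in a module."""
    from slannot.sim import SimConfig, simulate_dataset

    return simulate_dataset(SimConfig(seed=42))
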