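import numpy as np
import pytest

from mtbkit.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort shared across read-only tests."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
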