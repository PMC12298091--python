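import numpy as np
import pytest

from iopscreen.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def phantom_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_cohort(phantom_config):
    """80 phantoms at 64 px, shared across read-only tests."""
    return generate_cohort(phantom_config, 80, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
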