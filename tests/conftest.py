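import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny deterministic desk-scale cohort shared across tests."""
    from dbtmc.phantom import PhantomParams, generate_cohort

    return generate_cohort(PhantomParams.easy_desk(10, 10, seed=7))
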