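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


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_mid(rng, n_carbons):
    """Dirichlet-random isotopologue distribution."""
    from gngflux import MID

    return MID("x", tuple(rng.dirichlet(np.ones(n_carbons + 1))))


@pytest.fixture
def random_mid_factory(rng):
    return lambda n: random_mid(rng, n)
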