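import numpy as np
import pytest

from cccsim import CCCParams, ConservedTriple, DEFAULT_CONSERVED


@pytest.fixture
def params():
    """Default cascade parameters with no leak (threshold well defined)."""
    return CCCParams(kin=0.9, kleak=0.0)


@pytest.fixture
def conserved():
    return DEFAULT_CONSERVED


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_params(rng, kleak=0.0):
    """A physically sensible random parameter draw for property tests."""
    return CCCParams(
        kin=rng.uniform(0.1, 2.0),
        kleak=kleak,
        kout=rng.uniform(0.5, 2.0),
        kc=rng.uniform(0.3, 3.0),
        kp=rng.uniform(0.3, 3.0),
        K0=10 ** rng.uniform(-4, -1),
        K1=10 ** rng.uniform(-4, -1),
    )


def random_conserved(rng):
    cpool = rng.uniform(0.5, 4.0)
    csum = rng.uniform(0.5, 4.0)
    return ConservedTriple.from_pool_sum(cpool, csum)
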