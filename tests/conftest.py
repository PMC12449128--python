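import numpy as np
import pytest

from beliefvar import task
from beliefvar.observer import ObserverSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def jars():
    return task.make_jars(18, 0.1, 0.91)


@pytest.fixture(scope="session")
def session(jars):
    """A full 3-block session (54 trials) with fixed randomness."""
    return task.build_session(jars, n_blocks=3, rng=np.random.default_rng(7))


@pytest.fixture
def rho_sigma_spec():
    return ObserverSpec("bayes_rho_sigma", {"rho": 2.45, "sigma": 0.1})
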