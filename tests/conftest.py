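import numpy as np
import pytest

from methkin import conditions, dyad_model


@pytest.fixture(scope="session")
def serum():
    return conditions.SERUM


@pytest.fixture(scope="session")
def two_i():
    """2i parameter set with the p1 relaxation starting from serum p1."""
    return conditions.two_i_after_switch()


@pytest.fixture(scope="session")
def serum_state(serum):
    return dyad_model.steady_state_dyads(serum)


@pytest.fixture(scope="session")
def course_times():
    """Eight sampling times over 0-14 days (hours)."""
    return np.array([0.0, 16.0, 32.0, 72.0, 120.0, 168.0, 240.0, 336.0])


def random_rate_params(rng, max_p=1.0):
    from methkin.types import RateParameters

    p1, p2, p3 = rng.uniform(0.0, max_p, size=3)
    return RateParameters(p1=float(p1), p2=float(p2), p3=float(p3))


def random_dyad_state(rng):
    from methkin.types import DyadStateVector

    w = rng.dirichlet(np.ones(6))
    return DyadStateVector.from_array(w)
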