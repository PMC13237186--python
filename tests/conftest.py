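import numpy as np
import pytest

from finslermri import gradient_table, uniform_directions

AXIAL = 1.7e-3
RADIAL = 0.2e-3
ISO = 0.7e-3
BVALUE = 1500.0


@pytest.fixture(scope="session")
def dirs81():
    return uniform_directions(81)


@pytest.fixture(scope="session")
def gtab81(dirs81):
    return gradient_table(dirs81, BVALUE)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_quartic_coefficients(rng, scale=1e-3):
    """Random (not necessarily positive) coefficient vectors."""
    return rng.normal(scale=scale, size=15)


def random_spd_quartic(rng, scale=1.0):
    """QuarticTensor with strictly positive profile (symmetrized square of SPD)."""
    from finslermri import symmetrized_square

    a = rng.normal(size=(3, 3))
    spd = a @ a.T + 0.3 * np.eye(3)
    return symmetrized_square(scale * spd)
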