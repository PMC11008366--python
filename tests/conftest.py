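import numpy as np
import pytest

from hbscreen.energies import SurrogateParams
from hbscreen.fixtures import load_roster, surrogate_matrix
from hbscreen.selectivity import BindingMatrix


@pytest.fixture(scope="session")
def roster64():
    return load_roster()


@pytest.fixture(scope="session")
def surrogate_m(roster64):
    """Noise-free surrogate binding matrix over the packaged roster."""
    return surrogate_matrix(roster64, SurrogateParams())


def random_matrix(codes, seed, low=-2.0, high=30.0):
    """Symmetric random binding matrix over the given codes."""
    rng = np.random.default_rng(seed)
    n = len(codes)
    A = rng.uniform(low, high, (n, n))
    return BindingMatrix(codes, (A + A.T) / 2.0)


#: parseable codes with >= 2 sites, handy for random-matrix tests
CODES_12 = [
    "HH-h", "NN-h", "HN-h", "NO-h", "HO-h", "OO-h",
    "HHN-h", "OHO-h", "HNH-h", "NNO-h", "HHH-h", "NNN-h",
]
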