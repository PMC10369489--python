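import numpy as np
import pytest

from dimergrow import make_dimer, make_monomer
from dimergrow.landscape import cached_landscape


@pytest.fixture(scope="session")
def termini_monomer():
    """50-residue pseudo-monomer with two 15-residue terminal arms."""
    return make_monomer(50, shape="with-termini", termini_length=15, seed=7)


@pytest.fixture(scope="session")
def spherical_monomer():
    return make_monomer(50, shape="spherical", seed=7)


@pytest.fixture(scope="session")
def closed_loop_dimer(termini_monomer):
    """Dimer posed at (theta, phi) = (90, 90) through the SASA pipeline."""
    return make_dimer(termini_monomer, 90.0, 90.0)


@pytest.fixture(scope="session")
def default_landscape():
    return cached_landscape()


def random_rotation(rng):
    """Uniform random rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
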