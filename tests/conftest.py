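import numpy as np
import pytest

from spinpair import (
    NucleusSpec,
    RadicalPairSystem,
    load_fixture,
    point_dipole_tensor,
)


@pytest.fixture(scope="session")
def toy_system():
    """Packaged two-nitrogen model (Z = 9)."""
    return load_fixture("toy")


@pytest.fixture(scope="session")
def bare_pair():
    """Two electrons, no nuclei, no dipolar coupling, 50 uT field."""
    return RadicalPairSystem(nuclei=(), dipolar_static=np.zeros((3, 3)))


@pytest.fixture(scope="session")
def one_proton_pair():
    """One spin-1/2 nucleus with isotropic coupling a on radical 1, B = D = 0."""
    a = 0.5  # mT
    nuc = NucleusSpec("H", 1, 2, a * np.eye(3))
    return RadicalPairSystem(
        nuclei=(nuc,), dipolar_static=np.zeros((3, 3)), field_strength=0.0
    ), a


def random_symmetric(rng, scale=1.0):
    m = rng.normal(scale=scale, size=(3, 3))
    return 0.5 * (m + m.T)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250930)
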