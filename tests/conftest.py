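import numpy as np
import pytest

from thalparc.shmath import SHBasis
from thalparc.sphere import icosphere


@pytest.fixture(scope="session")
def basis():
    """Default-resolution lmax=6 basis (2562 sphere directions)."""
    return SHBasis(6)


@pytest.fixture(scope="session")
def coarse_basis():
    """Coarser tessellation for speed-sensitive tests (642 directions)."""
    return SHBasis(6, icosphere(3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_grid():
    """Reduced phantom geometry used by the heavier simulation tests."""
    return (14, 16, 12)
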