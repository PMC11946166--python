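import numpy as np
import pytest

from opusnirs import (
    build_sensitivity,
    default_brite_montage,
    default_scouts,
    spherical_cap_mesh,
)


@pytest.fixture(scope="session")
def montage():
    return default_brite_montage()


@pytest.fixture(scope="session")
def mesh(montage):
    return spherical_cap_mesh(montage=montage)


@pytest.fixture(scope="session")
def sensitivity(montage, mesh):
    return build_sensitivity(montage, mesh)


@pytest.fixture(scope="session")
def scouts(mesh):
    return default_scouts(mesh)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
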