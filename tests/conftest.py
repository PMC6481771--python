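import numpy as np
import pytest

from plumavis import (
    Spectrum,
    d65_illuminant,
    default_grid,
    dichromat_predator_viewer,
    parrot_viewer,
    peafowl_viewer,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def illum():
    return d65_illuminant()


@pytest.fixture(scope="session")
def flat_spectrum():
    def make(level=1.0, grid_nm=None, kind="reflectance"):
        g = grid_nm if grid_nm is not None else default_grid()
        return Spectrum(g, np.full(len(g), level), kind=kind)

    return make


@pytest.fixture(scope="session")
def peafowl():
    return peafowl_viewer()


@pytest.fixture(scope="session")
def parrot():
    return parrot_viewer()


@pytest.fixture(scope="session")
def predator():
    return dichromat_predator_viewer()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
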