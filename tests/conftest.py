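import numpy as np
import pytest

from lamcsd.circuit import default_mass_parameters
from lamcsd.inversion import LatentModel
from lamcsd.spectral import default_spectral_parameters


@pytest.fixture(scope="session")
def params():
    return default_mass_parameters()


@pytest.fixture(scope="session")
def spectral_params():
    return default_spectral_parameters()


@pytest.fixture(scope="session")
def gamma_grid():
    return np.arange(30.0, 81.0)


@pytest.fixture(scope="session")
def wide_grid():
    return np.arange(1.0, 101.0)


@pytest.fixture(scope="session")
def gamma_model(gamma_grid):
    return LatentModel(gamma_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
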