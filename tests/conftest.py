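import numpy as np
import pytest

from selva.raster import RasterGrid
from selva.synth import SynthConfig, generate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """50x50 landscape at the default study conditions (m=100, rho=0.5)."""
    return generate_landscape(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def nonspatial_landscape():
    """Landscape with sigma2=0 and rho=0: degenerates to the plain probit DGP."""
    return generate_landscape(SynthConfig(seed=5, rho=0.0, sigma2=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def grid_from(values, mask=None, resolution=900.0):
    return RasterGrid(np.asarray(values, dtype=float), mask, resolution)
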