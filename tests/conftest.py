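import numpy as np
import pytest

from ecoclues.grids import GridRaster, LandUseMap
from ecoclues.synthio import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def scene100():
    """One 100x100 synthetic scene with the default (strong) coefficients."""
    return generate_scene(SceneSpec(n_rows=100, n_cols=100, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_map(rng):
    """Random 50x50 six-class land-use map, 1 km cells."""
    return LandUseMap(rng.integers(1, 7, size=(50, 50)))


def make_raster(values, cell_size_km=1.0, mask=None):
    return GridRaster(np.asarray(values, dtype=float), cell_size_km, mask)
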