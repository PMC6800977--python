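import numpy as np
import pytest

from nichefill import EnvRaster, make_landscape


@pytest.fixture(scope="session")
def small_landscape():
    return make_landscape(seed=17, size=(80, 80), n_water_bodies=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def km_raster():
    """9x9 projected-km grid with a nodata hole."""
    vals = np.arange(81, dtype=float).reshape(9, 9)
    vals[4, 4] = np.nan
    return EnvRaster(vals, origin=(0.0, 9.0), cell_size=(1.0, 1.0), crs_id="synthetic-km")
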