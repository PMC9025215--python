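import numpy as np
import pandas as pd
import pytest

from rangeshift import synthetic_data as sd
from rangeshift.grid import GridSpec


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(nrows=40, ncols=40, xmin=0.0, ymin=40.0, cellsize=0.1)


@pytest.fixture(scope="session")
def climate_pair(small_grid):
    """(elevation, current climate) on the small grid, seed 7."""
    elev = sd.gen_elevation(7, small_grid.shape, grid=small_grid)
    cur = sd.gen_climate(7, small_grid.shape, grid=small_grid, elevation=elev)
    return elev, cur


@pytest.fixture(scope="session")
def truth_raster(climate_pair):
    _, cur = climate_pair
    return sd.true_suitability(cur)


@pytest.fixture()
def records_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lon": [1.0, 2.0, 3.0, 4.0],
            "lat": [41.0, 42.0, 43.0, 44.0],
            "year": [2000, 1969, 2010, 1995],
            "coord_uncertainty_m": [100.0, 100.0, 9250.0, 20000.0],
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
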