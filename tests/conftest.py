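import numpy as np
import pytest

from landhab.grid import GridSpec, LandUseRaster
from landhab.synth import (
    SyntheticScenario,
    generate_drivers,
    generate_landuse_series,
)


@pytest.fixture
def spec3():
    return GridSpec(3, 3, cell_size=1000.0)


@pytest.fixture
def checkerboard():
    spec = GridSpec(4, 4, cell_size=1000.0)
    codes = np.indices((4, 4)).sum(axis=0) % 2 + 1
    return LandUseRaster(spec, codes.astype(np.int64))


def random_landscape(rng, rows=8, cols=8, n_classes=3, cell=100.0,
                     nodata_frac=0.0):
    spec = GridSpec(rows, cols, cell_size=cell)
    codes = rng.integers(1, n_classes + 1, size=(rows, cols)).astype(np.int64)
    if nodata_frac > 0:
        hole = rng.random((rows, cols)) < nodata_frac
        if hole.all():
            hole[0, 0] = False
        codes[hole] = int(spec.nodata)
    return LandUseRaster(spec, codes)


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(spec=GridSpec(64, 64, cell_size=30.0), seed=11)


@pytest.fixture(scope="session")
def small_series(small_scenario):
    drivers = generate_drivers(small_scenario)
    series = generate_landuse_series(small_scenario, drivers)
    return drivers, series
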