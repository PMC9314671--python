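import numpy as np
import pytest

from cryosdm.grid import GEOGRAPHIC, EnvLayer, GridSpec


def make_grid(n_rows=10, n_cols=10, x0=-180.0, y_top=85.0, cell=0.5,
              crs=GEOGRAPHIC, nodata=-9999.0) -> GridSpec:
    return GridSpec(
        crs_id=crs, x0=x0, y_top=y_top, dx=cell, dy=cell,
        n_rows=n_rows, n_cols=n_cols, nodata_sentinel=nodata,
    )


def make_layer(grid: GridSpec, values, name="layer", valid=None) -> EnvLayer:
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(grid.shape, dtype=bool)
    return EnvLayer(name=name, values=values, valid_mask=np.asarray(valid, bool),
                    grid=grid)


@pytest.fixture
def small_grid():
    return make_grid(n_rows=10, n_cols=10, x0=0.0, y_top=60.0, cell=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
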