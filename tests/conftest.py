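import numpy as np
import pytest

from reforest.raster_core import Grid, GridGeometry, GridTransform
from reforest.synthetic import SyntheticConfig, generate_bundle, worked_example_bundle


def make_grid(values, *, west=0.0, north=1.0, px=None, res_class="coarse", **kw) -> Grid:
    """Grid from an array on a small near-equator box (uniform-ish areas)."""
    values = np.asarray(values)
    rows, cols = values.shape
    if px is None:
        px = 1.0 / max(rows, cols)
    t = GridTransform(origin_lon=west, origin_lat=north, px_width=px, px_height=px)
    return Grid(values, t, res_class=res_class, **kw)


def geometry(rows, cols, *, west=0.0, north=1.0, px=0.125) -> GridGeometry:
    return GridGeometry(
        GridTransform(origin_lon=west, origin_lat=north, px_width=px, px_height=px),
        (rows, cols),
    )


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=7, n_coarse=8, fine_factor=8, mid_factor=2)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def worked_bundle():
    return worked_example_bundle()
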