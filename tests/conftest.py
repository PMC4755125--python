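import numpy as np
import pytest

from popgrid import GridRaster, WorldConfig, generate_world
from popgrid.pipeline import run_pipeline


@pytest.fixture
def grid_3x3():
    return GridRaster(
        values=np.arange(9, dtype=float).reshape(3, 3),
        origin_x=0.0, origin_y=300.0, pixel_size=100.0, crs_id="local",
    )


@pytest.fixture(scope="session")
def small_cfg():
    """A miniature world: two census years, 25 model / 64 validation zones."""
    return WorldConfig(
        rows=60, cols=60, years=("1990", "2000"),
        n_coarse_zones=25, n_fine_zones=64, n_built_seeds=4, seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    return generate_world(small_cfg)


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions: 200x200 at 100 m, 3 years, 100/400 zones."""
    return generate_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_world):
    """Full pipeline run on the default world (500-tree forests)."""
    return run_pipeline(default_world, seed=7)
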