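import numpy as np
import pytest

from vegdyn.grids import GeoTransform, Grid
from vegdyn.pipeline import RunConfig, run_all


@pytest.fixture
def transform():
    return GeoTransform(x0=96.0, y0=36.0, dx=0.1, dy=-0.1)


@pytest.fixture
def small_grid(transform):
    vals = np.arange(12, dtype=float).reshape(3, 4) / 10.0
    return Grid(vals, transform)


@pytest.fixture(scope="session")
def default_run():
    """One shared end-to-end run of the default synthetic scene."""
    return run_all(RunConfig())
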