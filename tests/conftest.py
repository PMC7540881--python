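import numpy as np
import pytest

from elnm.raster import EnvStack, Grid, Layer


@pytest.fixture
def grid10():
    return Grid(10, 10, origin_lon=130.0, origin_lat=0.0, cell_size=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_layer(grid, values, name="x"):
    values = np.asarray(values, float)
    return Layer(grid, values, np.zeros(grid.shape, bool), name)


def make_stack(grid, arrays):
    """EnvStack from {name: 2-D array} with no nodata."""
    stack = EnvStack(grid)
    for name, arr in arrays.items():
        stack.add(name, make_layer(grid, arr, name))
    return stack


@pytest.fixture(scope="session")
def small_world():
    """A reduced synthetic world shared by tests that only need structure."""
    from elnm.synthetic import SyntheticWorldConfig, generate_world

    return generate_world(SyntheticWorldConfig(n_rows=120, n_cols=120, seed=11,
                                               villages_per_group=(40, 60)))


@pytest.fixture(scope="session")
def default_pipeline_result():
    """Full default-scale pipeline run (200x200, 8 groups), shared session-wide."""
    from elnm.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(seed=0))
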