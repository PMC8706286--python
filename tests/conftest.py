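import numpy as np
import pytest

from echemfp import SimulationConfig, generate_dataset
from echemfp.core import PotentialGrid, Voltammogram


@pytest.fixture(scope="session")
def small_config():
    """A cheap world: 5+2 taxa, 20 compounds, 2 replicates."""
    return SimulationConfig(
        n_ingroup=5, n_outgroup=2, n_replicates=2, n_compounds=20, seed=7
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_world():
    """The full 31+5 default world (seed 0)."""
    return generate_dataset(SimulationConfig(seed=0))


def make_trace(current, species="sp", condition="water_PBS", replicate=1, grid=None):
    grid = grid or PotentialGrid(0.0, 1.3, 1.3 / (len(current) - 1))
    return Voltammogram(species, condition, replicate, grid, np.asarray(current, float))


@pytest.fixture
def trace_factory():
    return make_trace
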