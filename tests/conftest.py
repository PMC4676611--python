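import numpy as np
import pytest

from myelosim.state import CellType, Grid, ModelParameters
from myelosim.synthetic_fixtures import FixtureSpec, make_grid_fixture


@pytest.fixture
def table_params():
    """Published constants with the equation-symbol amplitude binding (the
    reading used by the spec's worked examples)."""
    return ModelParameters(beta_binding="symbols")


@pytest.fixture
def calibrated_params():
    """The shipped calibrated defaults."""
    return ModelParameters()


@pytest.fixture
def small_grid():
    """5x5x5 grid with one cell of each type along the i axis."""
    spec = FixtureSpec(grid_shape=(5, 5, 5),
                       agents=[(CellType.MM, (2, 2, 2)),
                               (CellType.OB, (1, 2, 2)),
                               (CellType.OC, (3, 2, 2))])
    return make_grid_fixture(spec)


@pytest.fixture
def empty_grid():
    return Grid((5, 5, 5))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
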