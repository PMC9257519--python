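import numpy as np
import pytest

from rangeshift.grid import GridSpec
from rangeshift.synth import generate_environment


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """A 30x30 unit-cell grid used across the fast tests."""
    return GridSpec(x_min=0.0, y_min=0.0, cell_side=1.0, n_cols=30, n_rows=30)


@pytest.fixture(scope="session")
def env_stack(small_grid):
    """One deterministic synthetic environment shared by read-only tests."""
    return generate_environment(small_grid, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
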