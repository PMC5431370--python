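import numpy as np
import pytest

from memfhn import GridSpec, MediaState, ModelParams


@pytest.fixture
def params():
    """Default model coefficients (spiral-supporting induction gain)."""
    return ModelParams()


@pytest.fixture
def small_grid():
    """A quick 16x16 grid with unit spacing for oracle comparisons."""
    return GridSpec(n_rows=16, n_cols=16, L=16.0, h=0.01, duration=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_state(small_grid, rng):
    """A random but tame media state (u kept away from the -mu2 pole)."""
    shape = small_grid.shape
    u = rng.uniform(0.0, 1.0, shape)
    v = rng.uniform(0.0, 1.0, shape)
    phi = rng.uniform(-0.5, 0.5, shape)
    return MediaState(u, v, phi, t=0.0)
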