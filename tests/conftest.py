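import numpy as np
import pytest

from ndicube.cube import GapCube
from ndicube.synthetic import SyntheticSpec, make_synthetic_cube


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small, fast synthetic cube with 5 seasonal cycles (period 24)."""
    spec = SyntheticSpec(ny=8, nx=8, T=120, season=24, n_clusters=2, seed=3)
    return make_synthetic_cube(spec)


@pytest.fixture
def tiny_cube(rng):
    """3x3 grid, 10 dates, some gaps and one fully missing date."""
    vals = rng.uniform(-0.5, 0.9, size=(10, 3, 3))
    vals[2, 1, 1] = np.nan
    vals[7] = np.nan
    return GapCube(values=vals, time_days=np.arange(10.0) * 5.0)
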