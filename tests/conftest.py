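import numpy as np
import pytest

from nethomog.io import NetworkMask, Volume4D
from nethomog.simulate import RegionSpec, SimulationConfig, sphere_voxels


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_volume(rng):
    return Volume4D(data=rng.standard_normal((6, 5, 4, 30)))


@pytest.fixture
def full_mask():
    return NetworkMask(grid=np.ones((6, 5, 4), dtype=bool))


def tiny_config(seed=0, **kw):
    """A 10^3-grid, 2-region config small enough for per-test simulation."""
    grid = kw.pop("grid_dims", (10, 10, 10))
    regions = kw.pop("regions", None)
    if regions is None:
        regions = (
            RegionSpec("front", sphere_voxels((3, 3, 3), 1.6, grid), 0.6, 0.6),
            RegionSpec("back", sphere_voxels((7, 7, 7), 1.6, grid), 0.6, 0.6),
        )
    kw.setdefault("n_timepoints", 60)
    kw.setdefault("n_patients", 3)
    kw.setdefault("n_controls", 3)
    kw.setdefault("covariate_model", {})
    return SimulationConfig(grid_dims=grid, regions=regions, seed=seed, **kw)
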