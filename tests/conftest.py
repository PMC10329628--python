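import numpy as np
import pytest

from attachnet.dataset import DatasetConfig, generate_dataset
from attachnet.geometry import fit_grid, voxelize
from attachnet.synthetic_anatomy import OrganShapeSpec, generate_organ

# one procedural organ shared by most tests; 1280 faces keeps the
# brute-force geometry oracles affordable
ORGAN_SEED = 1
GRID_DIMS = (12, 12, 10)


@pytest.fixture(scope="session")
def organ_mesh():
    return generate_organ(OrganShapeSpec(seed=ORGAN_SEED), faces=1280)


@pytest.fixture(scope="session")
def organ_grid(organ_mesh):
    return fit_grid(organ_mesh, GRID_DIMS)


@pytest.fixture(scope="session")
def hex_model(organ_mesh, organ_grid):
    return voxelize(organ_mesh, organ_grid)


@pytest.fixture(scope="session")
def small_dataset(organ_mesh, hex_model, tmp_path_factory):
    """10 simulated samples with F=3 frames on the session organ."""
    path = tmp_path_factory.mktemp("data") / "small.h5"
    cfg = DatasetConfig(n_samples=10, frames=3, grid_dims=GRID_DIMS, seed=11)
    generate_dataset(organ_mesh, cfg, path, model=hex_model)
    return path, cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
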