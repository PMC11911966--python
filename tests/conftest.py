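import numpy as np
import pytest

from seasonstruct import synthetic
from seasonstruct.pointcloud import PointCloud


@pytest.fixture(scope="session")
def pool():
    return synthetic.generate_species_pool(12, 4, seed=11)


@pytest.fixture(scope="session")
def design(pool):
    return synthetic.generate_design(
        pool, n_blocks=3, plots_per_richness=2, mixtures_per_richness=4, seed=11
    )


@pytest.fixture(scope="session")
def inventories(design, pool):
    trees, truth = synthetic.generate_inventories(design, pool, seed=11)
    return trees, truth


def random_cloud(n=1000, seed=0, xyz_scale=(10.0, 10.0, 5.0), max_returns=3):
    """Uniform random cloud with consistent return numbering."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, xyz_scale[0], n)
    y = rng.uniform(0, xyz_scale[1], n)
    z = rng.uniform(0, xyz_scale[2], n)
    nor = rng.integers(1, max_returns + 1, n)
    rn = np.array([rng.integers(1, k + 1) for k in nor])
    return PointCloud(x=x, y=y, z=z, return_number=rn, number_of_returns=nor)


@pytest.fixture
def uniform_cloud():
    return random_cloud(n=2000, seed=42)
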