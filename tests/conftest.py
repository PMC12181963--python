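import numpy as np
import pytest

from ifpmap import (
    Density,
    Partition,
    PiecewiseLinearMap,
    TransferMatrix,
    make_ground_truth_map,
)


@pytest.fixture
def unit_partition() -> Partition:
    """Eight equal cells on [0, 1)."""
    return Partition.uniform(0.0, 1.0, 8)


@pytest.fixture
def domain_partition() -> Partition:
    """The default log10-intensity domain, 16 cells on [0, 4)."""
    return Partition.uniform(0.0, 4.0, 16)


@pytest.fixture
def tent_map(unit_partition) -> PiecewiseLinearMap:
    return make_ground_truth_map("tent", unit_partition)


def random_stochastic_matrix(n: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(n), size=n)


def random_density(partition: Partition, seed) -> Density:
    rng = np.random.default_rng(seed)
    return Density.from_masses(partition, rng.dirichlet(np.ones(partition.n_cells)))
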