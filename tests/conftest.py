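import numpy as np
import pytest

from gripseg import ConnectivityMatrix, NetworkPartition, ROITimeSeries


@pytest.fixture
def toy_timeseries():
    """5 timepoints x 3 regions, fixed values with non-trivial correlations."""
    values = np.array([
        [1.0, 2.0, 0.5],
        [2.0, 1.5, 1.0],
        [3.0, 3.5, 0.2],
        [4.0, 2.5, 1.8],
        [5.0, 4.0, 0.9],
    ])
    return ROITimeSeries("toy", values, ("ra", "rb", "rc"))


@pytest.fixture
def two_block_partition():
    """4 regions in 2 networks of 2."""
    return NetworkPartition({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, ("A", "B"))


@pytest.fixture
def two_block_matrix():
    """Prepared matrix: all within edges 0.6, all between edges 0.2."""
    ids = ("a1", "a2", "b1", "b2")
    z = np.full((4, 4), 0.2)
    z[0, 1] = z[1, 0] = 0.6
    z[2, 3] = z[3, 2] = 0.6
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix("blocky", z, ids, prepared=True)


def random_partition(rng, region_ids, max_networks=4):
    """Random partition where every network gets at least 2 regions."""
    region_ids = list(region_ids)
    n = len(region_ids)
    k = int(rng.integers(2, min(max_networks, n // 2) + 1))
    labels = [f"N{j}" for j in range(k)]
    # guarantee two regions per network, then assign the rest at random
    order = rng.permutation(n)
    assignment = {}
    for j, lab in enumerate(labels):
        assignment[region_ids[order[2 * j]]] = lab
        assignment[region_ids[order[2 * j + 1]]] = lab
    for idx in order[2 * k:]:
        assignment[region_ids[idx]] = labels[int(rng.integers(0, k))]
    return NetworkPartition(assignment, tuple(labels))


def random_prepared_matrix(rng, region_ids):
    """Random symmetric non-negative matrix with zero diagonal."""
    n = len(region_ids)
    z = np.abs(rng.normal(0.3, 0.2, (n, n)))
    z = np.triu(z, k=1)
    z = z + z.T
    return ConnectivityMatrix("rand", z, tuple(region_ids), prepared=True)
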