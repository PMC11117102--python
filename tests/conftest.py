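import numpy as np
import pytest

from frustnet import RegionPartition, SignedNetwork, generate_partition


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture
def small_partition():
    """60 regions, 10 equal networks, even hemisphere split."""
    return generate_partition(60, [6] * 10, (30, 30), seed=1)


@pytest.fixture
def four_net_partition():
    """60 regions in 4 unequal networks (for null-formula checks)."""
    return generate_partition(60, [10, 14, 16, 20], (28, 32), seed=2)


def make_signed(matrix_upper: np.ndarray) -> SignedNetwork:
    """Build a SignedNetwork from an upper-triangle sign specification."""
    signs = np.asarray(matrix_upper, dtype=np.int8)
    signs = np.triu(signs, 1)
    signs = signs + signs.T
    return SignedNetwork(signs)


@pytest.fixture
def k4_one_negative():
    """Complete graph on 4 nodes, single negative edge (0, 1)."""
    signs = np.ones((4, 4), dtype=np.int8)
    signs[0, 1] = signs[1, 0] = -1
    np.fill_diagonal(signs, 0)
    return SignedNetwork(signs)
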