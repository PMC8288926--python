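import numpy as np
import pytest

from genperc.core import MultiplexNetwork


@pytest.fixture
def chain_cross_net():
    """4-node worked example: layer A a path 0-1-2-3, layer B the two
    chords (0,2) and (1,3).  Hand enumeration gives psi = 1, 1/2, 1/4 and
    steady state after generation 3."""
    return MultiplexNetwork(4, [[(0, 1), (1, 2), (2, 3)], [(0, 2), (1, 3)]])


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_edge_set(rng, n_nodes, n_edges):
    """Random simple undirected edge set (possibly fewer than n_edges)."""
    u = rng.integers(0, n_nodes, size=n_edges)
    v = rng.integers(0, n_nodes, size=n_edges)
    keep = u != v
    lo, hi = np.minimum(u[keep], v[keep]), np.maximum(u[keep], v[keep])
    if len(lo) == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.column_stack([lo, hi]), axis=0)
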