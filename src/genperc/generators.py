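"""Network ensembles and fixtures for generational percolation studies.

Provides Erdős–Rényi layers in the fixed-edge-count ensemble G(N, M),
truncated power-law configuration-model layers, top-weight thresholding of
weighted matrices into sparse layers (the construction used for weighted
connectome data), and a synthetic weighted bilayer with tunable inter-layer
weight correlation that emulates a functional/morphological brain matrix
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MultiplexNetwork

__all__ = [
    "DegreeDistribution",
    "WeightedLayerPair",
    "er_layer",
    "sf_layer",
    "threshold_top_weights",
    "synthetic_weighted_pair",
    "layer_overlap",
    "er_multiplex",
    "sf_multiplex",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Truncated power law p_k ∝ k^{-gamma} on integer support {m, ..., K}.

    The normalization is numeric; the closed-form constant
    c ≈ (gamma-1) m^{gamma-1} is only the large-K approximation and is not
    used.
    """

    gamma: float
    m: int
    K: int
    k: np.ndarray = field(init=False, repr=False)
    p_k: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        if not 1 <= self.m <= self.K:
            raise ValueError("need 1 <= m <= K")
        k = np.arange(self.m, self.K + 1, dtype=np.int64)
        w = k.astype(float) ** (-self.gamma)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "p_k", w / w.sum())

    @property
    def mean(self) -> float:
        return float(self.k @ self.p_k)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.k, size=size, p=self.p_k)


@dataclass(frozen=True)
class WeightedLayerPair:
    """Two symmetric N×N weight matrices over a shared node set."""

    weights_a: np.ndarray
    weights_b: np.ndarray

    def __post_init__(self):
        for w in (self.weights_a, self.weights_b):
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise ValueError("weight matrices must be square")
            if not np.all(np.isfinite(w)):
                raise ValueError("weight matrices must be finite")
            if not np.allclose(w, w.T, atol=1e-8):
                raise ValueError("weight matrices must be symmetric")
        if self.weights_a.shape != self.weights_b.shape:
            raise ValueError("layer matrices must have the same shape")

    @property
    def n_nodes(self) -> int:
        return self.weights_a.shape[0]


def _edges_needed(n_nodes: int, z: float) -> int:
    m_edges = int(round(z * n_nodes / 2.0))
    if m_edges < 0 or m_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError(f"average degree {z} infeasible for N={n_nodes}")
    return m_edges


def er_layer(n_nodes: int, z: float, rng) -> np.ndarray:
    """Uniform simple graph with exactly M = round(z N / 2) edges (G(N, M)).

    The fixed-edge-count ensemble pins the control parameter (the average
    degree) exactly, removing ensemble noise in z.
    """
    rng = np.random.default_rng(rng)
    m_edges = _edges_needed(n_nodes, z)
    if m_edges == 0:
        return np.empty((0, 2), dtype=np.int64)
    # rejection sampling of distinct unordered pairs, vectorized via pair codes
    codes = np.empty(0, dtype=np.int64)
    while len(codes) < m_edges:
        draw = max(2 * (m_edges - len(codes)), 1024)
        u = rng.integers(0, n_nodes, size=draw)
        v = rng.integers(0, n_nodes, size=draw)
        ok = u != v
        lo, hi = np.minimum(u[ok], v[ok]), np.maximum(u[ok], v[ok])
        codes = np.unique(np.concatenate([codes, lo * n_nodes + hi]))
    codes = rng.choice(codes, size=m_edges, replace=False)
    return np.column_stack([codes // n_nodes, codes % n_nodes])


def sf_layer(n_nodes: int, gamma: float, m: int, K: int | None = None, rng=None) -> np.ndarray:
    """Configuration-model layer with truncated power-law degrees.

    Degrees are sampled i.i.d. from ``DegreeDistribution(gamma, m, K)`` with
    K defaulting to floor(sqrt(N)); if the degree sum is odd the last node's
    degree is resampled until the sum is even.  Stubs are paired uniformly
    and the multigraph is then simplified (self-loops dropped, multi-edges
    collapsed — the erased configuration model).
    """
    rng = np.random.default_rng(rng)
    if K is None:
        K = int(np.floor(np.sqrt(n_nodes)))
    if K > n_nodes - 1:
        raise ValueError("maximum degree K cannot exceed N-1")
    dist = DegreeDistribution(gamma, m, K)
    degrees = dist.sample(n_nodes, rng)
    if m == K and (n_nodes * m) % 2 == 1:
        raise ValueError("degree sum parity cannot be fixed for a regular sequence")
    while degrees.sum() % 2 == 1:
        degrees[-1] = dist.sample(1, rng)[0]
    stubs = np.repeat(np.arange(n_nodes, dtype=np.int64), degrees)
    rng.shuffle(stubs)
    u, v = stubs[0::2], stubs[1::2]
    keep = u != v
    lo, hi = np.minimum(u[keep], v[keep]), np.maximum(u[keep], v[keep])
    return np.unique(np.column_stack([lo, hi]), axis=0)


def threshold_top_weights(weights: np.ndarray, z: float, atol: float = 1e-8) -> np.ndarray:
    """Keep exactly the M = round(z N / 2) node pairs with the largest weights.

    Ties are broken deterministically: weight descending, then (i, j)
    lexicographic on the upper triangle.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(weights, weights.T, atol=atol):
        raise ValueError("weight matrix is not symmetric within tolerance")
    n = weights.shape[0]
    m_edges = _edges_needed(n, z)
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    order = np.lexsort((ju, iu, -w))[:m_edges]
    edges = np.column_stack([iu[order], ju[order]])
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


def synthetic_weighted_pair(
    n_nodes: int,
    rho: float,
    n_communities: int = 0,
    community_boost: float = 0.5,
    rng=None,
) -> WeightedLayerPair:
    """Synthetic bilayer of correlated weight matrices (connectome stand-in).

    Upper-triangle entries of the two matrices are jointly standard Gaussian
    with correlation ``rho``; with ``n_communities`` > 0, pairs inside the
    same (equal-sized) community receive an additive boost in both layers so
    that thresholding yields community-dense layers.  Thresholded layer
    overlap increases monotonically with ``rho``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(rng)
    iu, ju = np.triu_indices(n_nodes, k=1)
    z1 = rng.standard_normal(len(iu))
    z2 = rng.standard_normal(len(iu))
    wa = z1
    wb = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2
    if n_communities > 0:
        comm = np.arange(n_nodes) * n_communities // n_nodes
        same = comm[iu] == comm[ju]
        wa = wa + community_boost * same
        wb = wb + community_boost * same
    a = np.zeros((n_nodes, n_nodes))
    b = np.zeros((n_nodes, n_nodes))
    a[iu, ju] = wa
    b[iu, ju] = wb
    return WeightedLayerPair(a + a.T, b + b.T)


def layer_overlap(net: MultiplexNetwork) -> dict:
    """Link overlap of a two-layer multiplex.

    Reports the intersection and union sizes plus the overlap ratios
    intersection/union and intersection relative to each layer ("fraction of
    the total number" is reported in all three variants since the phrase is
    ambiguous for layers of unequal size).
    """
    if net.n_layers != 2:
        raise ValueError("layer_overlap is defined for two-layer networks")
    a, b = net.layers
    n = net.n_nodes
    ca = a[:, 0] * n + a[:, 1]
    cb = b[:, 0] * n + b[:, 1]
    inter = len(np.intersect1d(ca, cb, assume_unique=True))
    union = len(ca) + len(cb) - inter
    return {
        "size_a": len(ca),
        "size_b": len(cb),
        "intersection": inter,
        "union": union,
        "jaccard": inter / union if union else 1.0,
        "frac_of_a": inter / len(ca) if len(ca) else 1.0,
        "frac_of_b": inter / len(cb) if len(cb) else 1.0,
    }


def er_multiplex(n_nodes: int, z: float, rng, n_layers: int = 2) -> MultiplexNetwork:
    """Multiplex of independent ER layers with common average degree z."""
    rng = np.random.default_rng(rng)
    return MultiplexNetwork(n_nodes, [er_layer(n_nodes, z, rng) for _ in range(n_layers)])


def sf_multiplex(
    n_nodes: int, gamma: float, m: int, K: int | None = None, rng=None, n_layers: int = 2
) -> MultiplexNetwork:
    """Multiplex of independent configuration-model layers."""
    rng = np.random.default_rng(rng)
    return MultiplexNetwork(
        n_nodes, [sf_layer(n_nodes, gamma, m, K, rng) for _ in range(n_layers)]
    )
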