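"""Deterministic history-dependent percolation engine.

A multiplex network is a single set of ``N`` nodes carrying two or more
layers of undirected links.  The generational percolation process applies
the layers cyclically: generation ``n`` keeps an edge of the active layer
only if its endpoints belong to the same cluster of the previous
configuration ``C^{n-1}``, and the clusters of the surviving edges form
``C^n``.  Starting from the universal configuration ``C^0`` (all nodes in
one cluster), each generation therefore *refines* the previous partition,
so the process always reaches a steady state after finitely many
generations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


__all__ = [
    "MultiplexNetwork",
    "Partition",
    "GenerationTrace",
    "components",
    "apply_layer",
    "percolate_generations",
    "dilute",
    "edge_marks",
    "occupy",
]


def _as_edge_array(edges, n_nodes: int) -> np.ndarray:
    """Canonicalize an edge collection to a sorted (M, 2) int array with u < v.

    Self-loops are rejected; duplicate undirected edges are collapsed.
    """
    arr = np.asarray(sorted((min(u, v), max(u, v)) for u, v in edges) if not isinstance(edges, np.ndarray) else edges, dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr.reshape(-1, 2)
    lo = np.minimum(arr[:, 0], arr[:, 1])
    hi = np.maximum(arr[:, 0], arr[:, 1])
    if np.any(lo == hi):
        raise ValueError("self-loops are not allowed in a layer")
    if lo.min() < 0 or hi.max() >= n_nodes:
        raise ValueError(f"node id out of range [0, {n_nodes})")
    arr = np.unique(np.column_stack([lo, hi]), axis=0)
    return arr


@dataclass(frozen=True)
class MultiplexNetwork:
    """Shared node set of size ``n_nodes`` plus an ordered list of edge layers.

    Each layer is stored canonically as an (M, 2) integer array with
    ``u < v`` per row, unique rows, no self-loops.
    """

    n_nodes: int
    layers: tuple[np.ndarray, ...]

    def __init__(self, n_nodes: int, layers):
        if n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        layers = tuple(_as_edge_array(layer, n_nodes) for layer in layers)
        if len(layers) < 2:
            raise ValueError("a multiplex network needs at least two layers")
        object.__setattr__(self, "n_nodes", int(n_nodes))
        object.__setattr__(self, "layers", layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def edge_counts(self) -> list[int]:
        return [len(layer) for layer in self.layers]


@dataclass(frozen=True)
class Partition:
    """Cluster assignment of ``N`` nodes with canonical labels.

    The label of every cluster is the smallest node id it contains, so two
    equal partitions have identical label arrays and comparison is O(N).
    """

    labels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64))

    @classmethod
    def universal(cls, n_nodes: int) -> "Partition":
        return cls(np.zeros(n_nodes, dtype=np.int64))

    @classmethod
    def singletons(cls, n_nodes: int) -> "Partition":
        return cls(np.arange(n_nodes, dtype=np.int64))

    @classmethod
    def from_component_labels(cls, comp: np.ndarray) -> "Partition":
        """Canonicalize arbitrary component labels to min-node-id labels."""
        n = comp.shape[0]
        n_comp = int(comp.max()) + 1 if n else 0
        min_node = np.full(n_comp, n, dtype=np.int64)
        np.minimum.at(min_node, comp, np.arange(n, dtype=np.int64))
        return cls(min_node[comp])

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        """Cluster sizes in descending order."""
        sizes = np.bincount(self.labels, minlength=self.n_nodes)
        sizes = sizes[sizes > 0]
        return np.sort(sizes)[::-1]

    def largest(self) -> int:
        return int(self.cluster_sizes()[0])

    def second_largest(self) -> int:
        sizes = self.cluster_sizes()
        return int(sizes[1]) if len(sizes) > 1 else 0

    def size_histogram(self) -> Counter:
        """Counter mapping cluster size -> number of clusters of that size."""
        return Counter(self.cluster_sizes().tolist())

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and np.array_equal(self.labels, other.labels)

    def refines(self, other: "Partition") -> bool:
        """True if every cluster of self lies inside one cluster of other."""
        # self refines other iff the map self-label -> other-label is a function
        pairs = np.unique(np.column_stack([self.labels, other.labels]), axis=0)
        return len(np.unique(pairs[:, 0])) == len(pairs)


@dataclass
class GenerationTrace:
    """Per-generation record of the history-dependent percolation process.

    ``psi[n-1]`` is the largest-cluster fraction at generation ``n``;
    ``second_largest`` counts nodes; ``n_c`` is the smallest ``n`` with
    ``C^{n+1} = C^n`` (the last generation that changed anything); entries
    recorded beyond ``n_c`` are constant by construction.
    """

    psi: list[float] = field(default_factory=list)
    second_largest: list[int] = field(default_factory=list)
    n_clusters: list[int] = field(default_factory=list)
    histograms: list[Counter] = field(default_factory=list)
    partitions: list[Partition] | None = None
    n_c: int | None = None
    converged: bool = False

    @property
    def n_generations(self) -> int:
        return len(self.psi)

    def psi_at(self, n: int) -> float:
        """psi at generation n (1-based); constant beyond the recorded trace."""
        if n < 1:
            raise ValueError("generations are 1-based")
        return self.psi[min(n, len(self.psi)) - 1]

    def final_psi(self) -> float:
        return self.psi[-1]


def components(edges: np.ndarray, n_nodes: int) -> Partition:
    """Connected components of an undirected edge set over [0, N)."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if len(edges) == 0:
        return Partition.singletons(n_nodes)
    data = np.ones(len(edges), dtype=np.int8)
    graph = coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n_nodes, n_nodes))
    _, comp = connected_components(graph, directed=False)
    return Partition.from_component_labels(comp)


def apply_layer(partition: Partition, layer: np.ndarray) -> Partition:
    """One generation step: components of the layer edges whose endpoints
    share a cluster in ``partition``.  The result refines ``partition``."""
    layer = np.asarray(layer, dtype=np.int64).reshape(-1, 2)
    n = partition.n_nodes
    if len(layer) and (layer.min() < 0 or layer.max() >= n):
        raise ValueError("layer references node ids outside the partition")
    labels = partition.labels
    keep = labels[layer[:, 0]] == labels[layer[:, 1]] if len(layer) else np.empty(0, bool)
    return components(layer[keep], n)


def percolate_generations(
    net: MultiplexNetwork,
    max_generations: int = 10_000,
    stop_at_steady: bool = True,
    keep_partitions: bool = False,
    keep_histograms: bool = True,
) -> GenerationTrace:
    """Run the generational process until steady state (or the cap).

    ``C^0`` is the universal single cluster, so generation 1 is the plain
    connected components of the first layer.  Layers are used cyclically.
    For two layers, a single application that leaves the partition unchanged
    certifies the steady state (applying a layer is idempotent); for more
    layers a full unchanged cycle is required.
    """
    if max_generations < 1:
        raise ValueError("max_generations must be positive")
    trace = GenerationTrace(partitions=[] if keep_partitions else None)
    part = Partition.universal(net.n_nodes)
    L = net.n_layers
    unchanged_run = 0
    # one unchanged application suffices at L=2, but only once the partition
    # was itself produced by a layer application (i.e. from generation 2 on)
    needed = 1 if L == 2 else L
    for n in range(1, max_generations + 1):
        new = apply_layer(part, net.layers[(n - 1) % L])
        changed = new != part
        part = new
        sizes = part.cluster_sizes()
        trace.psi.append(float(sizes[0]) / net.n_nodes)
        trace.second_largest.append(int(sizes[1]) if len(sizes) > 1 else 0)
        trace.n_clusters.append(len(sizes))
        if keep_histograms:
            trace.histograms.append(Counter(sizes.tolist()))
        if trace.partitions is not None:
            trace.partitions.append(part)
        if changed:
            unchanged_run = 0
        elif n >= 2:
            unchanged_run += 1
            if unchanged_run >= needed and not trace.converged:
                trace.converged = True
                trace.n_c = n - unchanged_run
                if stop_at_steady:
                    break
    if stop_at_steady and not trace.converged and max_generations >= net.n_nodes + 2:
        # partitions over a finite set refine at most N-1 times; unreachable
        raise RuntimeError("steady state not detected within the refinement bound")
    return trace


def dilute(net: MultiplexNetwork, p: float, seed: int) -> MultiplexNetwork:
    """Bond dilution: retain each link of each layer independently with
    probability ``p``.  Reproducible given ``seed``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("occupation probability p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kept = [layer[rng.random(len(layer)) < p] for layer in net.layers]
    return MultiplexNetwork(net.n_nodes, kept)


def edge_marks(net: MultiplexNetwork, seed: int) -> list[np.ndarray]:
    """Draw one uniform mark per edge per layer, for coupled p-sweeps: the
    occupied sets ``{mark < p}`` are nested across p, giving monotone sweeps."""
    rng = np.random.default_rng(seed)
    return [rng.random(len(layer)) for layer in net.layers]


def occupy(net: MultiplexNetwork, marks: list[np.ndarray], p: float) -> MultiplexNetwork:
    """Sub-network of edges whose mark is below ``p`` (coupled dilution)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("occupation probability p must lie in [0, 1]")
    kept = [layer[m < p] for layer, m in zip(net.layers, marks)]
    return MultiplexNetwork(net.n_nodes, kept)
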