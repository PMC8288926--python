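"""Engine unit and property tests: worked examples, the BFS oracle, and the
structural invariants of the generational refinement process."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from genperc.core import (MultiplexNetwork, Partition, apply_layer, components,
                          dilute, edge_marks, occupy, percolate_generations)
from conftest import random_edge_set


def bfs_partition(edges, n_nodes):
    """Independent oracle: connected components via networkx BFS."""
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(map(tuple, edges))
    labels = np.empty(n_nodes, dtype=np.int64)
    for comp in nx.connected_components(g):
        root = min(comp)
        for node in comp:
            labels[node] = root
    return Partition(labels)


class TestComponents:
    def test_empty_edges_gives_singletons(self):
        assert components(np.empty((0, 2), int), 5) == Partition.singletons(5)

    def test_path_with_isolate(self):
        part = components(np.array([[0, 1], [1, 2]]), 4)
        assert part.labels.tolist() == [0, 0, 0, 3]

    def test_matches_bfs_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 65))
            edges = random_edge_set(rng, n, int(rng.integers(0, 3 * n + 1)))
            assert components(edges, n) == bfs_partition(edges, n)


class TestApplyLayer:
    def test_universal_partition_gives_plain_components(self, rng):
        n = 30
        edges = random_edge_set(rng, n, 40)
        out = apply_layer(Partition.universal(n), edges)
        assert out == components(edges, n)

    def test_singletons_are_absorbing(self, rng):
        n = 20
        edges = random_edge_set(rng, n, 30)
        assert apply_layer(Partition.singletons(n), edges) == Partition.singletons(n)

    def test_hand_enumerated_split(self):
        # clusters {0,1,2},{3}; edge (2,3) crosses and is filtered out
        part = Partition(np.array([0, 0, 0, 3]))
        out = apply_layer(part, np.array([[0, 1], [2, 3]]))
        assert out.labels.tolist() == [0, 0, 2, 3]

    def test_result_refines_input(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            base = components(random_edge_set(rng, n, n), n)
            out = apply_layer(base, random_edge_set(rng, n, n))
            assert out.refines(base)

    def test_idempotence(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            part = components(random_edge_set(rng, n, n), n)
            layer = random_edge_set(rng, n, n)
            once = apply_layer(part, layer)
            assert apply_layer(once, layer) == once


class TestPercolateGenerations:
    def test_worked_example_psi_sequence(self, chain_cross_net):
        trace = percolate_generations(chain_cross_net)
        assert trace.psi[:3] == [1.0, 0.5, 0.25]
        assert trace.n_c == 3
        assert trace.converged

    def test_worked_example_intermediate_clusters(self, chain_cross_net):
        trace = percolate_generations(chain_cross_net, keep_partitions=True)
        # generation 2: clusters {0,2} and {1,3}
        assert trace.partitions[1].labels.tolist() == [0, 1, 0, 1]
        assert trace.partitions[2] == Partition.singletons(4)

    def test_identical_layers_reach_steady_at_generation_one(self, rng):
        n = 40
        a = random_edge_set(rng, n, 50)
        trace = percolate_generations(MultiplexNetwork(n, [a, a]))
        assert trace.n_c == 1
        assert all(p == trace.psi[0] for p in trace.psi)

    def test_empty_second_layer_shatters_everything(self):
        net = MultiplexNetwork(4, [[(0, 1), (1, 2), (2, 3)], []])
        trace = percolate_generations(net)
        assert trace.psi[0] == 1.0
        assert trace.psi[1] == 0.25
        assert trace.n_c == 2

    def test_generation_one_is_plain_components_of_layer_a(self, rng):
        n = 50
        a = random_edge_set(rng, n, 60)
        b = random_edge_set(rng, n, 60)
        trace = percolate_generations(MultiplexNetwork(n, [a, b]),
                                      keep_partitions=True)
        assert trace.partitions[0] == components(a, n)

    def test_psi_non_increasing_and_nc_bounded(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 60))
            net = MultiplexNetwork(n, [random_edge_set(rng, n, 2 * n),
                                       random_edge_set(rng, n, 2 * n)])
            trace = percolate_generations(net)
            assert trace.converged and trace.n_c <= n
            assert all(a >= b - 1e-12 for a, b in zip(trace.psi, trace.psi[1:]))

    def test_refinement_chain(self, rng):
        n = 40
        net = MultiplexNetwork(n, [random_edge_set(rng, n, 60),
                                   random_edge_set(rng, n, 60)])
        trace = percolate_generations(net, keep_partitions=True)
        for prev, cur in zip(trace.partitions, trace.partitions[1:]):
            assert cur.refines(prev)

    def test_cluster_sizes_sum_to_n(self, rng):
        n = 35
        net = MultiplexNetwork(n, [random_edge_set(rng, n, 40),
                                   random_edge_set(rng, n, 40)])
        trace = percolate_generations(net, keep_partitions=True)
        for part in trace.partitions:
            assert part.cluster_sizes().sum() == n

    def test_three_layer_cycle(self):
        # three layers must be applied cyclically; a full unchanged cycle
        # certifies the steady state
        net = MultiplexNetwork(4, [[(0, 1), (2, 3)], [(0, 1), (1, 2)], [(1, 2)]])
        trace = percolate_generations(net)
        assert trace.converged
        # gen 1: {0,1},{2,3}; gen 2 keeps (0,1): {0,1},{2},{3};
        # gen 3: edge (1,2) crosses clusters -> all singletons, stable
        assert trace.psi[0] == 0.5
        assert trace.psi[1] == 0.5
        assert trace.final_psi() == 0.25
        assert trace.n_c == 3


class TestValidation:
    def test_rejects_single_layer(self):
        with pytest.raises(ValueError):
            MultiplexNetwork(3, [[(0, 1)]])

    def test_rejects_out_of_range_ids(self):
        with pytest.raises(ValueError):
            MultiplexNetwork(3, [[(0, 5)], [(0, 1)]])

    def test_rejects_self_loops(self):
        with pytest.raises(ValueError):
            MultiplexNetwork(3, [[(1, 1)], [(0, 1)]])

    def test_collapses_duplicate_edges(self):
        net = MultiplexNetwork(3, [[(0, 1), (1, 0), (0, 1)], [(1, 2)]])
        assert net.edge_counts() == [1, 1]


class TestDilution:
    def test_p_one_keeps_everything(self, chain_cross_net):
        out = dilute(chain_cross_net, 1.0, seed=1)
        assert out.edge_counts() == chain_cross_net.edge_counts()

    def test_p_zero_empties_layers(self, chain_cross_net):
        assert dilute(chain_cross_net, 0.0, seed=1).edge_counts() == [0, 0]

    def test_invalid_p_rejected(self, chain_cross_net):
        with pytest.raises(ValueError):
            dilute(chain_cross_net, 1.5, seed=1)

    def test_kept_count_binomial(self, rng):
        n, m = 2000, 100_000
        edges = random_edge_set(rng, n, int(m * 1.3))[:m]
        net = MultiplexNetwork(n, [edges, edges[:10]])
        kept = dilute(net, 0.5, seed=7).edge_counts()[0]
        m_eff = len(edges)
        sigma = np.sqrt(m_eff * 0.25)
        assert abs(kept - 0.5 * m_eff) < 4 * sigma

    def test_reproducible_given_seed(self, chain_cross_net):
        a = dilute(chain_cross_net, 0.5, seed=3)
        b = dilute(chain_cross_net, 0.5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a.layers, b.layers))

    def test_coupled_marks_are_nested_across_p(self, rng):
        n = 200
        net = MultiplexNetwork(n, [random_edge_set(rng, n, 400),
                                   random_edge_set(rng, n, 400)])
        marks = edge_marks(net, seed=5)
        small = occupy(net, marks, 0.3)
        large = occupy(net, marks, 0.7)
        for s, l in zip(small.layers, large.layers):
            codes_s = set(map(tuple, s))
            codes_l = set(map(tuple, l))
            assert codes_s <= codes_l

    def test_psi_monotone_under_nested_dilution(self, rng):
        # edge-subset layers can never percolate better, generation by generation
        n = 300
        net = MultiplexNetwork(n, [random_edge_set(rng, n, 700),
                                   random_edge_set(rng, n, 700)])
        marks = edge_marks(net, seed=11)
        t_small = percolate_generations(occupy(net, marks, 0.4), stop_at_steady=False,
                                        max_generations=6)
        t_large = percolate_generations(occupy(net, marks, 0.9), stop_at_steady=False,
                                        max_generations=6)
        for ps, pl in zip(t_small.psi, t_large.psi):
            assert ps <= pl + 1e-12


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.data())
def test_apply_layer_refinement_property(data):
    """Hypothesis: any generation step refines its input partition."""
    n = data.draw(st.integers(2, 24))
    edges1 = data.draw(st.sets(
        st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(lambda e: e[0] != e[1]),
        max_size=30))
    edges2 = data.draw(st.sets(
        st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(lambda e: e[0] != e[1]),
        max_size=30))
    canon = lambda es: np.array(sorted({(min(u, v), max(u, v)) for u, v in es}),
                                dtype=np.int64).reshape(-1, 2)
    base = components(canon(edges1), n)
    out = apply_layer(base, canon(edges2))
    assert out.refines(base)
    assert apply_layer(out, canon(edges2)) == out
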