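"""Quality-function unit and property tests for the core data model."""

import math

import networkx as nx
import numpy as np
import pytest

from modrefine.core import (Network, Partition, composite_score,
                            module_stats, modularity, partition_density,
                            qualifies_as_module, resolution_limits)

from conftest import random_network, random_partition


def brute_force_modularity(network, partition, gamma=1.0):
    """Independent evaluation from the adjacency/degree closed form.

    Q = (1/2L) * sum_ij [A_ij - gamma * d_i d_j / 2L] * delta(c_i, c_j),
    computed with dense numpy arrays — no per-module edge counting.
    """
    nodes = list(network.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in network.graph.edges():
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    d = A.sum(axis=1)
    L = network.L
    label_ids: dict = {}
    c = np.array([label_ids.setdefault(partition.assignment[v],
                                       len(label_ids)) for v in nodes])
    same = c[:, None] == c[None, :]
    B = A - gamma * np.outer(d, d) / (2.0 * L)
    return float(B[same].sum() / (2.0 * L))


class TestNetworkConstruction:
    def test_self_loops_and_duplicates_dropped(self):
        net = Network([(0, 1), (1, 0), (1, 1), (1, 2)])
        assert net.L == 2
        assert net.n_selfloops_dropped == 1
        assert net.n_duplicates_dropped == 1

    def test_degree_sum_is_twice_edge_count(self):
        net = random_network(25, 0.2, seed=3)
        assert sum(d for _, d in net.graph.degree()) == 2 * net.L


class TestModuleStats:
    def test_triangle_in_two_triangles(self, two_triangles):
        net, _ = two_triangles
        s = module_stats(net, {0, 1, 2})
        assert (s.n_m, s.l_m, s.theta_m) == (3, 3, 7)
        assert s.Q_m == pytest.approx(3 / 7 - (7 / 14) ** 2)

    def test_whole_network_quality_is_zero(self):
        net = random_network(20, 0.3, seed=1)
        s = module_stats(net, set(net.nodes))
        assert s.l_m == net.L and s.theta_m == 2 * net.L
        assert s.Q_m == pytest.approx(0.0, abs=1e-15)

    def test_singleton_quality_negative(self, two_triangles):
        net, _ = two_triangles
        s = module_stats(net, {2})
        d = net.degree(2)
        assert s.l_m == 0 and s.theta_out == d
        assert s.Q_m == pytest.approx(-((d / (2 * net.L)) ** 2))

    def test_invalid_inputs(self, two_triangles):
        net, _ = two_triangles
        with pytest.raises(ValueError):
            module_stats(net, set())
        with pytest.raises(ValueError):
            module_stats(net, {99})
        with pytest.raises(ValueError):
            module_stats(Network(nodes=[0, 1]), {0})


class TestModularity:
    def test_one_module_partition_is_zero(self, two_triangles):
        net, _ = two_triangles
        whole = Partition.from_modules([set(net.nodes)])
        assert modularity(net, whole) == pytest.approx(0.0, abs=1e-15)

    def test_two_triangles_hand_value(self, two_triangles):
        net, part = two_triangles
        assert modularity(net, part) == pytest.approx(2 * (3 / 7 - 0.25))

    def test_all_singletons_closed_form(self, two_triangles):
        net, _ = two_triangles
        singles = Partition({v: v for v in net.nodes})
        expected = -sum((net.degree(v) / (2 * net.L)) ** 2
                        for v in net.nodes)
        assert modularity(net, singles) == pytest.approx(expected)

    def test_invalid_partition_names_offender(self, two_triangles):
        net, _ = two_triangles
        with pytest.raises(ValueError, match="5"):
            modularity(net, Partition({v: 0 for v in range(5)}))

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("gamma", [1.0, 0.5, 2.0])
    def test_agrees_with_brute_force_on_random_graphs(self, seed, gamma):
        net = random_network(28, 0.25, seed=seed)
        if net.L == 0:
            pytest.skip("edgeless draw")
        part = random_partition(net, 4, seed=seed + 100)
        assert modularity(net, part, gamma) == pytest.approx(
            brute_force_modularity(net, part, gamma), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_networkx(self, seed):
        net = random_network(40, 0.15, seed=seed)
        part = random_partition(net, 5, seed=seed)
        communities = list(part.modules.values())
        assert modularity(net, part) == pytest.approx(
            nx.community.modularity(net.graph, communities), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_degree_and_edge_conservation(self, seed):
        net = random_network(30, 0.2, seed=seed)
        part = random_partition(net, 4, seed=seed + 7)
        stats = [module_stats(net, m) for m in part.modules.values()]
        assert sum(s.theta_m for s in stats) == 2 * net.L
        inter = sum(s.l_out for s in stats) // 2
        assert sum(s.l_m for s in stats) + inter == net.L


class TestQualification:
    def test_k5_with_one_external_edge(self, k5_in_40_edge_network):
        d = qualifies_as_module(k5_in_40_edge_network, set(range(5)))
        assert d.qualifies
        assert d.stats.theta_in == 20 and d.stats.theta_out == 1

    def test_boundary_a_equals_two_fails(self):
        # triangle (3 intra edges) with exactly 6 external edges: a = 2
        edges = [(0, 1), (1, 2), (0, 2)]
        edges += [(0, 3), (0, 4), (1, 5), (1, 6), (2, 7), (2, 8)]
        edges += [(3, 4), (5, 6), (7, 8), (3, 5)]
        net = Network(edges)
        d = qualifies_as_module(net, {0, 1, 2})
        assert d.stats.theta_in == d.stats.theta_out == 6
        assert not d.qualifies and not d.internal_exceeds_external

    def test_whole_network_fails_positivity(self, two_triangles):
        net, _ = two_triangles
        d = qualifies_as_module(net, set(net.nodes))
        assert not d.qualifies and not d.positive_quality

    def test_invariant_under_relabeling(self, two_k4_bridge):
        net, _ = two_k4_bridge
        mapping = {v: f"node_{v}" for v in net.nodes}
        relabeled = Network([(mapping[u], mapping[v])
                             for u, v in net.graph.edges()])
        before = qualifies_as_module(net, {0, 1, 2, 3})
        after = qualifies_as_module(relabeled,
                                    {mapping[v] for v in (0, 1, 2, 3)})
        assert before.qualifies == after.qualifies
        assert before.stats.Q_m == pytest.approx(after.stats.Q_m)


class TestResolutionLimits:
    def test_hand_values(self):
        lim = resolution_limits(800)
        assert lim.l_min == pytest.approx(20.0)
        assert lim.l_max == pytest.approx(200.0)
        assert lim.refinable_threshold == pytest.approx(40.0)

    def test_small_L(self):
        lim = resolution_limits(2)
        assert lim.l_min == pytest.approx(1.0)
        assert lim.l_max == pytest.approx(0.5)
        assert lim.refinable_threshold == pytest.approx(2.0)

    def test_monotone_in_L(self):
        prev = resolution_limits(1)
        for L in range(2, 300, 7):
            cur = resolution_limits(L)
            assert cur.l_min >= prev.l_min
            assert cur.l_max >= prev.l_max
            assert cur.refinable_threshold >= prev.refinable_threshold
            prev = cur

    def test_ordering_for_large_L(self):
        for L in (32, 100, 1000):
            lim = resolution_limits(L)
            assert lim.l_min < lim.refinable_threshold <= lim.l_max

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            resolution_limits(0)


class TestPartitionDensity:
    def test_disjoint_cliques_give_one(self):
        import itertools
        edges = []
        for base in (0, 5, 10):
            edges += [(base + u, base + v)
                      for u, v in itertools.combinations(range(5), 2)]
        net = Network(edges)
        part = Partition.from_modules([set(range(b, b + 5))
                                       for b in (0, 5, 10)])
        assert partition_density(net, part) == pytest.approx(1.0)

    def test_tree_module_contributes_zero(self):
        # a path (tree) plus a triangle elsewhere
        net = Network([(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (4, 6)])
        part = Partition.from_modules([{0, 1, 2, 3}, {4, 5, 6}])
        triangle_only = Partition.from_modules([{4, 5, 6},
                                                {0}, {1}, {2}, {3}])
        assert partition_density(net, part) == pytest.approx(
            partition_density(net, triangle_only))

    def test_two_k4_hand_value(self, two_k4_bridge):
        net, part = two_k4_bridge
        assert partition_density(net, part) == pytest.approx(12 / 13)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_by_one(self, seed):
        net = random_network(25, 0.3, seed=seed)
        part = random_partition(net, 4, seed=seed)
        assert partition_density(net, part) <= 1.0 + 1e-12


class TestCompositeScore:
    def test_additive(self, two_triangles):
        net, part = two_triangles
        assert composite_score(0.0, 0.0) == 0.0
        assert composite_score(0.5, 0.5) == 1.0
        q = modularity(net, part)
        pd_ = partition_density(net, part)
        assert composite_score(q, pd_) == pytest.approx(
            2 * (3 / 7 - 0.25) + 6 / 7)

    def test_strictly_increasing(self):
        assert composite_score(0.3, 0.2) < composite_score(0.31, 0.2)
        assert composite_score(0.3, 0.2) < composite_score(0.3, 0.21)
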