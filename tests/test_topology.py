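"""Modularity partitioning, eigenvector centrality, module matching."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metabodnm.exceptions import AlignmentError
from metabodnm.netinfer import MiNetwork
from metabodnm.topology import (
    ModulePartition,
    centrality_table,
    eigenvector_centrality,
    jaccard_matrix,
    leading_eigenvector_partition,
    match_modules,
    modularity,
)


def net_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_weighted_edges_from([(str(u), str(v), float(w)) for u, v, w in edges])
    return MiNetwork(g)


def exhaustive_best_q(net, max_groups=4):
    """Brute-force maximum modularity over all partitions into <= max_groups."""
    nodes = list(net.graph.nodes)
    n = len(nodes)
    best = -1.0
    for labels in itertools.product(range(max_groups), repeat=n):
        if labels[0] != 0:  # canonical first label to cut symmetry
            continue
        q = modularity(net, pd.Series(labels, index=nodes))
        best = max(best, q)
    return best


def power_iteration_centrality(net, iters=20_000):
    a = nx.to_numpy_array(net.graph, nodelist=list(net.graph.nodes), weight="weight")
    v = np.ones(a.shape[0])
    for _ in range(iters):
        v = a @ v
        v /= np.linalg.norm(v)
    return pd.Series(v / v.max(), index=list(net.graph.nodes))


class TestLeadingEigenvectorPartition:
    def test_two_cliques_match_exhaustive_optimum(self):
        edges = []
        for block, offset in ((range(5), 0), (range(5), 5)):
            for i, j in itertools.combinations(block, 2):
                edges.append((i + offset, j + offset, 1.0))
        edges.append((0, 5, 1.0))  # bridge
        net = net_from_edges(edges)
        part = leading_eigenvector_partition(net)
        groups = {frozenset(part.members(lab)) for lab in part.labels}
        expected = {frozenset(str(i) for i in range(5)), frozenset(str(i) for i in range(5, 10))}
        assert groups == expected
        assert part.Q == pytest.approx(exhaustive_best_q(net, max_groups=3), abs=1e-9)

    def test_complete_graph_single_module_q_zero(self):
        edges = [(i, j, 1.0) for i, j in itertools.combinations(range(6), 2)]
        part = leading_eigenvector_partition(net_from_edges(edges))
        assert len(part.labels) == 1
        assert part.Q == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_edges_q_half(self):
        part = leading_eigenvector_partition(net_from_edges([(0, 1, 1.0), (2, 3, 1.0)]))
        assert len(part.labels) == 2
        assert part.Q == pytest.approx(0.5)

    def test_q_contributions_sum_to_q(self, default_dataset):
        tensor, _ = default_dataset
        from metabodnm.netinfer import dpi_prune, pairwise_mi

        mi = pairwise_mi(
            pd.DataFrame(np.log2(tensor.values[:, :, 1]), index=tensor.metabolite_ids)
        )
        part = leading_eigenvector_partition(dpi_prune(mi))
        assert sum(part.q_contrib.values()) == pytest.approx(part.Q, abs=1e-10)
        assert -0.5 <= part.Q <= 1.0
        labs = sorted(part.q_contrib)
        assert labs == list(range(1, len(labs) + 1))  # contiguous from 1
        assert set(part.assignment) == set(labs)

    def test_isolated_nodes_become_singletons(self):
        net = net_from_edges([(0, 1, 1.0)], nodes=["0", "1", "iso1", "iso2"])
        part = leading_eigenvector_partition(net)
        assert part.assignment["iso1"] != part.assignment["iso2"]
        assert part.sizes()[part.assignment["iso1"]] == 1

    def test_matches_igraph_on_random_graph(self, rng):
        """Independent cross-check: Q at least as good as igraph's on the
        same graph (both are the same heuristic; minor tie-breaks differ)."""
        igraph = pytest.importorskip("igraph")
        g = nx.erdos_renyi_graph(40, 0.12, seed=7)
        nx.set_edge_attributes(g, 1.0, "weight")
        net = MiNetwork(g)
        part = leading_eigenvector_partition(net)
        ig = igraph.Graph.from_networkx(g)
        ig_part = ig.community_leading_eigenvector()
        q_ig = ig.modularity(ig_part)
        assert part.Q >= q_ig - 0.05


class TestEigenvectorCentrality:
    def test_star_graph_closed_form(self):
        edges = [(0, i, 1.0) for i in range(1, 5)]
        cent = eigenvector_centrality(net_from_edges(edges))
        assert cent["0"] == pytest.approx(1.0)
        for leaf in "1234":
            assert cent[leaf] == pytest.approx(0.5)  # 1/sqrt(deg) of centre

    def test_complete_graph_all_equal_one(self):
        edges = [(i, j, 1.0) for i, j in itertools.combinations(range(5), 2)]
        cent = eigenvector_centrality(net_from_edges(edges))
        np.testing.assert_allclose(cent.to_numpy(), 1.0)

    def test_weighted_triangle_matches_power_iteration(self):
        net = net_from_edges([(0, 1, 2.0), (1, 2, 1.0), (0, 2, 1.0)])
        cent = eigenvector_centrality(net)
        oracle = power_iteration_centrality(net)
        np.testing.assert_allclose(
            cent.to_numpy(), oracle.reindex(cent.index).to_numpy(), atol=1e-8
        )

    def test_random_graph_matches_power_iteration(self, rng):
        g = nx.erdos_renyi_graph(30, 0.2, seed=5)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
        net = MiNetwork(g)
        cent = eigenvector_centrality(net)
        oracle = power_iteration_centrality(net)
        np.testing.assert_allclose(
            cent.to_numpy(), oracle.reindex(cent.index).to_numpy(), atol=1e-8
        )

    def test_scale_invariance(self):
        edges = [(0, 1, 0.5), (1, 2, 0.25), (2, 3, 1.0)]
        c1 = eigenvector_centrality(net_from_edges(edges))
        c2 = eigenvector_centrality(net_from_edges([(u, v, 10 * w) for u, v, w in edges]))
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-10)

    def test_bounds_and_max_one(self, default_dataset):
        tensor, _ = default_dataset
        from metabodnm.netinfer import dpi_prune, pairwise_mi

        mi = pairwise_mi(
            pd.DataFrame(np.log2(tensor.values[:, :, 0]), index=tensor.metabolite_ids)
        )
        cent = eigenvector_centrality(dpi_prune(mi))
        assert cent.min() >= 0 and cent.max() == pytest.approx(1.0)


def partition_of(mapping, condition=""):
    s = pd.Series(mapping, name="module")
    labels = sorted(set(mapping.values()))
    return ModulePartition(s, 0.0, {lab: 0.0 for lab in labels}, condition)


class TestMatchModules:
    def test_identity_partitions(self):
        p = partition_of({"A": 1, "B": 1, "C": 2})
        m = match_modules(p, p)
        assert m.mapping == {1: 1, 2: 2}
        assert all(j == 1.0 for j in m.jaccard.values())
        assert not m.membership_changed.any()

    def test_single_move_flagged_once(self):
        p1 = partition_of({"A": 1, "B": 1, "C": 2, "D": 2})
        p2 = partition_of({"A": 1, "B": 1, "C": 1, "D": 2})
        m = match_modules(p1, p2)
        assert int(m.membership_changed.sum()) == 1
        assert m.membership_changed["C"]

    def test_matches_bruteforce_jaccard_argmax(self, rng):
        items = [f"M{i}" for i in range(322)]
        p_post = partition_of(dict(zip(items, rng.integers(1, 15, size=322))))
        p_fast = partition_of(dict(zip(items, rng.integers(1, 13, size=322))))
        m = match_modules(p_post, p_fast)
        jm = jaccard_matrix(p_fast, p_post)
        for lf in p_fast.labels:
            row = jm.loc[lf]
            assert row[m.mapping[lf]] == row.max()
            ties = row.index[row == row.max()]
            assert m.mapping[lf] == min(ties)

    def test_mismatched_sets_raise(self):
        p1 = partition_of({"A": 1, "B": 2})
        p2 = partition_of({"A": 1, "C": 2})
        with pytest.raises(AlignmentError):
            match_modules(p1, p2)


def test_centrality_table_paired_change():
    c1 = pd.Series({"A": 1.0, "B": 0.2})
    c2 = pd.Series({"A": 0.5, "B": 1.0})
    tab = centrality_table(c1, c2)
    assert tab.loc["A", "delta_c"] == pytest.approx(-0.5)
    assert tab.loc["B", "delta_c"] == pytest.approx(0.8)
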