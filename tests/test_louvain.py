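"""Modularity and Louvain optimization, cross-checked against closed forms,
exhaustive enumeration and networkx."""

import numpy as np
import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

import dietclust as dc
from dietclust.louvain import _aggregate, _modularity_adj, _to_adj

from conftest import knn_cluster, random_weighted_graph


def two_triangles():
    g = dc.WeightedGraph(6)
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        g.add_edge(a, b, 1.0)
    return g


def two_k4_bridge():
    g = dc.WeightedGraph(8)
    for base in (0, 4):
        for a in range(4):
            for b in range(a + 1, 4):
                g.add_edge(base + a, base + b, 1.0)
    g.add_edge(0, 4, 1.0)
    return g


def to_networkx(g):
    h = nx.Graph()
    h.add_nodes_from(range(g.n_nodes))
    for i, j, w in g.edges():
        h.add_edge(i, j, weight=w)
    return h


class TestModularity:
    def test_single_community_is_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = random_weighted_graph(rng, 7)
            assert dc.modularity(g, np.zeros(7, int)) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_natural_partition(self):
        q = dc.modularity(two_triangles(), [0, 0, 0, 1, 1, 1])
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_singleton_partition_is_negative(self):
        g = two_triangles()
        q = dc.modularity(g, np.arange(6))
        m = g.total_weight
        expect = -sum((g.weighted_degree(i) / (2 * m)) ** 2 for i in range(6))
        assert q == pytest.approx(expect, abs=1e-12)
        assert q < 0

    def test_agrees_with_networkx(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = random_weighted_graph(rng, 8)
            labels = rng.integers(0, 3, 8)
            coms = [set(np.flatnonzero(labels == c)) for c in range(3)]
            coms = [c for c in coms if c]
            expect = nx.algorithms.community.modularity(to_networkx(g), coms, weight="weight")
            assert dc.modularity(g, labels) == pytest.approx(expect, abs=1e-12)

    def test_resolution_scaling_matches_networkx(self):
        rng = np.random.default_rng(2)
        g = random_weighted_graph(rng, 8)
        labels = rng.integers(0, 2, 8)
        coms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        for gamma in (0.5, 1.7):
            expect = nx.algorithms.community.modularity(to_networkx(g), coms,
                                                        weight="weight", resolution=gamma)
            assert dc.modularity(g, labels, gamma) == pytest.approx(expect, abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            dc.modularity(dc.WeightedGraph(3), [0, 0, 0])


class TestLouvain:
    def test_two_triangles_recovered(self):
        part = dc.louvain(two_triangles(), dc.LouvainParams(seed=0))
        assert part.q == pytest.approx(0.5, abs=1e-12)
        assert part.n_communities == 2
        assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1

    def test_two_k4s_reach_exhaustive_optimum(self):
        g = two_k4_bridge()
        part = dc.louvain(g, dc.LouvainParams(seed=0))
        best = dc.exhaustive_best_partition(g)
        assert part.q == pytest.approx(best.q, abs=1e-9)
        assert adjusted_rand_score(part.labels, [0] * 4 + [1] * 4) == 1.0

    def test_q_trace_monotone_and_beats_singletons(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            g = random_weighted_graph(rng, 8)
            part = dc.louvain(g, dc.LouvainParams(seed=4))
            trace = np.asarray(part.q_trace)
            assert np.all(np.diff(trace) >= -1e-12)
            assert part.q >= dc.modularity(g, np.arange(8)) - 1e-12
            # reported Q matches a from-scratch recomputation
            assert part.q == pytest.approx(dc.modularity(g, part.labels), abs=1e-12)

    def test_aggregation_preserves_modularity(self):
        rng = np.random.default_rng(5)
        g = random_weighted_graph(rng, 8)
        adj = _to_adj(g)
        m = g.total_weight
        labels = np.array([0, 0, 1, 1, 2, 2, 1, 0])
        q_before = _modularity_adj(adj, labels, 1.0, m)
        agg = _aggregate(adj, labels)
        q_after = _modularity_adj(agg, np.arange(3), 1.0, m)
        assert q_after == pytest.approx(q_before, abs=1e-12)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        g = random_weighted_graph(rng, 8)
        a = dc.louvain(g, dc.LouvainParams(seed=9))
        b = dc.louvain(g, dc.LouvainParams(seed=9))
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.q == b.q

    def test_disconnected_components_stay_separate(self):
        g = dc.WeightedGraph(5)
        g.add_edge(0, 1, 1.0)
        g.add_edge(2, 3, 1.0)
        part = dc.louvain(g, dc.LouvainParams(seed=0))
        assert part.labels[0] == part.labels[1]
        assert part.labels[2] == part.labels[3]
        assert part.labels[4] not in (part.labels[0], part.labels[2])

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            dc.louvain(dc.WeightedGraph(4), dc.LouvainParams())

    def test_stability_across_seeds_on_planted_data(self):
        cfg = dc.GeneratorConfig(n_subjects=500, n_fa_clusters=6, seed=17)
        cohort = dc.generate_cohort(cfg)
        matrix = dc.build_intake_matrix(cohort, "fatty_acids")
        params = dc.KnnParams()
        graph = dc.build_graph(dc.knn_search(matrix, params), matrix, params)
        parts = [dc.louvain(graph, dc.LouvainParams(seed=s)).labels for s in range(20)]
        aris = [adjusted_rand_score(parts[i], parts[j])
                for i in range(20) for j in range(i + 1, 20)]
        assert min(aris) >= 0.95


class TestRelabelBySize:
    def test_decreasing_size_order(self):
        part = dc.Partition(labels=np.array([1, 1, 1, 0, 0, 2]), q=0.1)
        out = dc.relabel_by_size(part)
        assert out.labels.tolist() == [0, 0, 0, 1, 1, 2]
        assert out.sizes.tolist() == [3, 2, 1]

    def test_idempotent(self):
        part = dc.Partition(labels=np.array([0, 0, 1, 2]), q=0.0)
        once = dc.relabel_by_size(part)
        twice = dc.relabel_by_size(once)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_equal_sizes_ordered_by_first_member(self):
        part = dc.Partition(labels=np.array([5, 3, 5, 3]), q=0.0)
        out = dc.relabel_by_size(part)
        assert out.labels.tolist() == [0, 1, 0, 1]


def test_recovery_on_planted_cohort(recovery_cohort):
    """The benchmark regime: 8 fatty-acid communities recovered with high
    agreement and strong modularity."""
    _, _, part = knn_cluster(recovery_cohort, "fatty_acids")
    truth = dc.planted_truth(recovery_cohort).to_numpy()
    assert part.n_communities == 8
    assert adjusted_rand_score(truth, part.labels) >= 0.9
    assert part.q >= 0.6
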