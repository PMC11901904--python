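"""K-NN search, cosine weighting and network construction, cross-checked
against brute-force and scikit-learn oracles."""

import numpy as np
import pytest
from sklearn.neighbors import NearestNeighbors

import dietclust as dc
from dietclust.derive import IntakeMatrix


def matrix_from(values):
    values = np.asarray(values, float)
    return IntakeMatrix(values=values, subjects=np.arange(len(values)),
                        variables=[f"v{i}" for i in range(values.shape[1])],
                        standardized=False,
                        raw_means=values.mean(0), raw_sds=values.std(0))


class TestKnnSearch:
    def test_three_points_on_a_line(self):
        m = matrix_from([[0.0], [1.0], [10.0]])
        nb = dc.knn_search(m, dc.KnnParams(k=1))
        assert nb[:, 0].tolist() == [1, 0, 1]

    def test_duplicate_points_tie_broken_by_index(self):
        m = matrix_from([[1.0, 2.0]] * 4)
        nb = dc.knn_search(m, dc.KnnParams(k=1))
        # everyone's nearest is the smallest other index
        assert nb[:, 0].tolist() == [1, 0, 0, 0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 7))
        m = matrix_from(x)
        nb = dc.knn_search(m, dc.KnnParams(k=10))
        # oracle: exhaustive pairwise distances, independent ordering
        d = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d, np.inf)
        oracle = np.argsort(d, axis=1, kind="stable")[:, :10]
        np.testing.assert_array_equal(nb, oracle)
        # and sklearn agrees
        sk = NearestNeighbors(n_neighbors=11).fit(x).kneighbors(x)[1][:, 1:]
        np.testing.assert_array_equal(nb, sk)

    def test_input_validation(self):
        m = matrix_from([[0.0], [1.0]])
        with pytest.raises(ValueError):
            dc.knn_search(m, dc.KnnParams(k=2))
        bad = matrix_from([[0.0], [np.nan]])
        with pytest.raises(ValueError):
            dc.knn_search(bad, dc.KnnParams(k=1))


class TestCosine:
    def test_identities(self):
        u = np.array([1.0, 2.0, -3.0])
        assert dc.cosine_similarity(u, u) == pytest.approx(1.0, abs=1e-12)
        assert dc.cosine_similarity(u, -u) == pytest.approx(-1.0, abs=1e-12)
        assert dc.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u, v = rng.normal(size=5), rng.normal(size=5)
            expect = float(u @ v) / np.sqrt(float(u @ u) * float(v @ v))
            assert dc.cosine_similarity(u, v) == pytest.approx(expect, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            dc.cosine_similarity([0, 0], [1, 0])


class TestBuildGraph:
    def test_union_degree_bound(self):
        # all-positive vectors: every cosine weight is positive, so no edge
        # is similarity-filtered and the union bound must hold
        rng = np.random.default_rng(2)
        m = matrix_from(rng.uniform(1.0, 2.0, size=(50, 4)))
        params = dc.KnnParams(k=5)
        g = dc.build_graph(dc.knn_search(m, params), m, params)
        assert all(len(g.adj[i]) >= 5 for i in range(50))

    def test_mutual_is_subset_of_union(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.normal(size=(40, 3)))
        pu = dc.KnnParams(k=4, symmetrization="union")
        pm = dc.KnnParams(k=4, symmetrization="mutual")
        gu = dc.build_graph(dc.knn_search(m, pu), m, pu)
        gm = dc.build_graph(dc.knn_search(m, pm), m, pm)
        assert gm.n_edges <= gu.n_edges
        for i, j, _ in gm.edges():
            assert gu.has_edge(i, j)

    def test_weights_are_cosines_and_positive(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 5))
        m = matrix_from(x)
        params = dc.KnnParams(k=4)
        g = dc.build_graph(dc.knn_search(m, params), m, params)
        for i, j, w in g.edges():
            assert 0 < w <= 1 + 1e-12
            assert w == pytest.approx(dc.cosine_similarity(x[i], x[j]), abs=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(25, 4))
        perm = rng.permutation(25)
        params = dc.KnnParams(k=3)
        g1 = dc.build_graph(dc.knn_search(matrix_from(x), params), matrix_from(x), params)
        g2 = dc.build_graph(dc.knn_search(matrix_from(x[perm]), params), matrix_from(x[perm]), params)
        inv = np.argsort(perm)
        e1 = {(min(i, j), max(i, j)): w for i, j, w in g1.edges()}
        e2 = {(min(perm[i], perm[j]), max(perm[i], perm[j])): w for i, j, w in g2.edges()}
        assert set(e1) == set(e2)
        for k in e1:
            assert e1[k] == pytest.approx(e2[k], abs=1e-12)

    def test_snn_weights_are_jaccard(self):
        rng = np.random.default_rng(6)
        m = matrix_from(rng.normal(size=(20, 3)))
        params = dc.KnnParams(k=4, weight_scheme="snn")
        nb = dc.knn_search(m, params)
        g = dc.build_graph(nb, m, params)
        sets = [set(map(int, row)) | {i} for i, row in enumerate(nb)]
        for i, j, w in g.edges():
            assert w == pytest.approx(len(sets[i] & sets[j]) / len(sets[i] | sets[j]))

    def test_separated_clusters_have_few_between_edges(self, recovery_cohort):
        m = dc.build_intake_matrix(recovery_cohort, "fatty_acids")
        params = dc.KnnParams()
        g = dc.build_graph(dc.knn_search(m, params), m, params)
        truth = dc.planted_truth(recovery_cohort).loc[m.subjects].to_numpy()
        between = sum(w for i, j, w in g.edges() if truth[i] != truth[j])
        assert between / g.total_weight < 0.10

    def test_two_well_separated_clusters_have_few_between_edges(self):
        cfg = dc.GeneratorConfig(n_subjects=400, n_fa_clusters=2, cluster_separation=4.0,
                                 effect_table=(), seed=19)
        cohort = dc.generate_cohort(cfg)
        m = dc.build_intake_matrix(cohort, "fatty_acids")
        params = dc.KnnParams()
        g = dc.build_graph(dc.knn_search(m, params), m, params)
        truth = dc.planted_truth(cohort).loc[m.subjects].to_numpy()
        between_count = sum(1 for i, j, _ in g.edges() if truth[i] != truth[j])
        assert between_count / g.n_edges < 0.05


def test_graph_type_invariants():
    g = dc.WeightedGraph(3)
    with pytest.raises(ValueError):
        g.add_edge(1, 1, 0.5)
    with pytest.raises(ValueError):
        g.add_edge(0, 1, 0.0)
    g.add_edge(0, 1, 0.4)
    g.add_edge(1, 2, 0.6)
    assert g.total_weight == pytest.approx(1.0)
    assert g.weighted_degree(1) == pytest.approx(1.0)
    assert g.n_edges == 2
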