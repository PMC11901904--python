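import numpy as np
import pytest

import dietclust as dc


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared across tests (150 subjects, 4 + 5
    planted clusters, strong separation)."""
    cfg = dc.GeneratorConfig(n_subjects=150, n_fa_clusters=4, n_spread_clusters=8,
                             effect_table=(), seed=11)
    return dc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def derived_cohort(small_cohort):
    return dc.derive_outcomes(small_cohort)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The benchmark recovery regime: 800 subjects, 8 fatty-acid and 10
    spread clusters, separation 3 SD."""
    cfg = dc.GeneratorConfig(n_subjects=800, n_fa_clusters=8, n_spread_clusters=10,
                             cluster_separation=3.0, seed=7)
    return dc.derive_outcomes(dc.generate_cohort(cfg))


def knn_cluster(cohort, variable_set, seed=1, k=20):
    """Convenience: matrix -> knn graph -> louvain -> size-ordered labels."""
    matrix = dc.build_intake_matrix(cohort, variable_set)
    params = dc.KnnParams(k=k)
    graph = dc.build_graph(dc.knn_search(matrix, params), matrix, params)
    return matrix, graph, dc.relabel_by_size(dc.louvain(graph, dc.LouvainParams(seed=seed)))


def random_weighted_graph(rng, n_nodes, p_edge=0.5):
    """Random connected-ish weighted graph for oracle comparisons."""
    g = dc.WeightedGraph(n_nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(i, j, float(rng.uniform(0.2, 1.0)))
    if g.total_weight == 0:
        g.add_edge(0, 1, 1.0)
    return g
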