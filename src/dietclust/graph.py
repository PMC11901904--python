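"""K-nearest-neighbor network construction.

Subjects are linked to their K most similar subjects in intake space
(exact search; at cohort scale approximate indexing would be pointless) and
the retained pairs are weighted by the cosine similarity of the two
subjects' standardized intake profiles.  Non-positive weights are dropped by
default because modularity optimization assumes non-negative edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .derive import IntakeMatrix

__all__ = ["KnnParams", "WeightedGraph", "knn_search", "cosine_similarity", "build_graph"]

log = logging.getLogger(__name__)


@dataclass
class KnnParams:
    k: int = 20
    metric: str = "euclidean"
    symmetrization: str = "union"   # "union" | "mutual"
    min_similarity: float = 0.0     # edges with weight <= this are dropped
    weight_scheme: str = "cosine"   # "cosine" | "snn" (shared-neighbor Jaccard)

    def validate(self, n: int) -> None:
        if not 1 <= self.k < n:
            raise ValueError(f"need 1 <= K < n_subjects, got K={self.k}, n={n}")
        if self.min_similarity < 0:
            raise ValueError("min_similarity must be >= 0 (edge weights must stay positive)")
        if self.symmetrization not in ("union", "mutual"):
            raise ValueError(f"unknown symmetrization {self.symmetrization!r}")
        if self.weight_scheme not in ("cosine", "snn"):
            raise ValueError(f"unknown weight_scheme {self.weight_scheme!r}")


class WeightedGraph:
    """Undirected graph with strictly positive edge weights and no self-loops.

    Nodes are integers 0..n-1 (row positions of the intake matrix); the
    mapping to subject ids is kept alongside.
    """

    def __init__(self, n_nodes: int, subjects=None):
        self.n_nodes = int(n_nodes)
        self.subjects = np.arange(n_nodes) if subjects is None else np.asarray(subjects)
        self.adj: list[dict[int, float]] = [dict() for _ in range(self.n_nodes)]

    def add_edge(self, i: int, j: int, weight: float) -> None:
        if i == j:
            raise ValueError("self-loops are not allowed")
        if weight <= 0:
            raise ValueError("edge weights must be positive")
        self.adj[i][j] = float(weight)
        self.adj[j][i] = float(weight)

    def has_edge(self, i: int, j: int) -> bool:
        return j in self.adj[i]

    def edges(self):
        """Iterate (i, j, weight) with i < j."""
        for i in range(self.n_nodes):
            for j, w in self.adj[i].items():
                if i < j:
                    yield i, j, w

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adj) // 2

    @property
    def total_weight(self) -> float:
        """m = sum of edge weights over undirected edges."""
        return sum(sum(a.values()) for a in self.adj) / 2.0

    def weighted_degree(self, i: int) -> float:
        return sum(self.adj[i].values())

    def to_edge_dataframe(self) -> pd.DataFrame:
        rows = [(self.subjects[i], self.subjects[j], w) for i, j, w in self.edges()]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def knn_search(matrix: IntakeMatrix, params: KnnParams) -> np.ndarray:
    """Exact K-nearest-neighbor lists.

    Returns an (n, K) integer array: row i holds the K nearest other
    subjects under the metric, nearest first; distance ties are broken by
    the smaller subject index so results are deterministic.
    """
    x = matrix.values
    params.validate(x.shape[0])
    if np.isnan(x).any():
        raise ValueError("intake matrix contains NaN")
    d = cdist(x, x, metric=params.metric)
    np.fill_diagonal(d, np.inf)
    n = x.shape[0]
    idx = np.arange(n)
    # lexsort: primary key distance, secondary key column index (tie-break)
    order = np.lexsort((np.broadcast_to(idx, (n, n)), d), axis=1)
    return order[:, : params.k]


def cosine_similarity(u, v) -> float:
    """u.v / (|u||v|), in [-1, 1]; zero vectors are rejected."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(u @ v / (nu * nv))


def build_graph(neighbors: np.ndarray, matrix: IntakeMatrix, params: KnnParams) -> WeightedGraph:
    """Symmetrize the directed K-NN lists into a weighted graph.

    Under ``union`` a pair linked in either direction becomes an edge; under
    ``mutual`` both directions are required.  Edge weight is the cosine
    similarity of the two subjects' intake vectors (or, with
    ``weight_scheme="snn"``, the Jaccard overlap of their neighbor lists).
    Edges with weight <= ``min_similarity`` are dropped, so the graph may be
    disconnected.
    """
    x = matrix.values
    n = x.shape[0]
    if neighbors.shape[0] != n:
        raise ValueError("neighbor lists do not match the matrix")
    pairs = set()
    directed = {(i, int(j)) for i in range(n) for j in neighbors[i]}
    for i, j in directed:
        a, b = (i, j) if i < j else (j, i)
        if params.symmetrization == "union" or (j, i) in directed:
            pairs.add((a, b))

    graph = WeightedGraph(n, subjects=matrix.subjects)
    norms = np.linalg.norm(x, axis=1)
    nbr_sets = [set(map(int, row)) | {i} for i, row in enumerate(neighbors)]
    n_dropped = 0
    for i, j in pairs:
        if params.weight_scheme == "cosine":
            if norms[i] == 0 or norms[j] == 0:
                raise ValueError("cosine weight undefined for a zero intake vector")
            w = float(x[i] @ x[j] / (norms[i] * norms[j]))
        else:
            inter = len(nbr_sets[i] & nbr_sets[j])
            w = inter / len(nbr_sets[i] | nbr_sets[j])
        if w > params.min_similarity:
            graph.add_edge(i, j, w)
        else:
            n_dropped += 1
    if n_dropped:
        log.info("dropped %d K-NN pairs with similarity <= %g (modularity needs "
                 "non-negative weights)", n_dropped, params.min_similarity)
    return graph
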