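"""Multi-level Louvain modularity optimization, written from first principles.

Modularity of a partition of a weighted graph is

    Q = (1/2m) * sum_ij [A_ij - gamma * k_i * k_j / (2m)] * delta(c_i, c_j)

with A_ij the edge weight, k_i the weighted degree, m the total edge weight
and gamma the resolution.  The algorithm alternates (1) greedy single-node
moves to the neighboring community with the largest positive modularity
gain, sweeping nodes in a seeded shuffled order until no move improves Q,
and (2) aggregation of communities into super-nodes (intra-community weight
becoming self-loops), repeating until a full pass yields no improvement.

Node-visit order is the only source of randomness; a fixed seed gives an
identical partition.  An exhaustive-enumeration optimizer over all set
partitions is included for cross-checking on tiny graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import WeightedGraph

__all__ = [
    "LouvainParams",
    "Partition",
    "modularity",
    "louvain",
    "relabel_by_size",
    "exhaustive_best_partition",
]


@dataclass
class LouvainParams:
    resolution: float = 1.0
    seed: int = 0
    max_passes: int = 100
    tolerance: float = 1e-7  # minimum modularity gain to accept a move / pass
    n_restarts: int = 5      # independent sweep orders; the best-Q run wins

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class Partition:
    """Node -> community assignment with its modularity.

    Community ids are contiguous from 0; ``labels[i]`` is the community of
    graph node i (row position), ``subjects`` carries the subject ids.
    """

    labels: np.ndarray
    q: float
    subjects: np.ndarray = None
    q_trace: list = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_communities)

    def to_dataframe(self) -> pd.DataFrame:
        subj = self.subjects if self.subjects is not None else np.arange(self.labels.size)
        return pd.DataFrame({
            "subject_id": subj,
            "cluster_id": self.labels,
            "cluster_label": [f"C{c}" for c in self.labels],
        })


# --- internal adjacency representation: list of {neighbor: weight} dicts,
# self-loop weight stored once at adj[i][i], degree counts it twice ---------

def _to_adj(graph: WeightedGraph) -> list[dict[int, float]]:
    return [dict(nbrs) for nbrs in graph.adj]


def _degrees(adj) -> np.ndarray:
    return np.array([sum(nbrs.values()) + nbrs.get(i, 0.0) for i, nbrs in enumerate(adj)])


def _total_weight(adj) -> float:
    m = 0.0
    for i, nbrs in enumerate(adj):
        for j, w in nbrs.items():
            m += w if j == i else 0.5 * w
    return m


def _modularity_adj(adj, labels, gamma, m) -> float:
    intra = np.zeros(int(max(labels)) + 1)
    for i, nbrs in enumerate(adj):
        for j, w in nbrs.items():
            if labels[i] == labels[j]:
                intra[labels[i]] += w if j == i else 0.5 * w
    deg = _degrees(adj)
    deg_sum = np.bincount(labels, weights=deg, minlength=intra.size)
    return float(np.sum(intra / m - gamma * (deg_sum / (2.0 * m)) ** 2))


def modularity(graph: WeightedGraph, partition, resolution: float = 1.0) -> float:
    """Modularity Q of a partition on its graph.

    ``partition`` may be a :class:`Partition` or any array of per-node
    community labels.  Raises on an empty graph (m = 0).
    """
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if labels.shape[0] != graph.n_nodes:
        raise ValueError("partition does not cover the graph's nodes")
    m = graph.total_weight
    if m <= 0:
        raise ValueError("modularity undefined on a graph with no edge weight")
    _, labels = np.unique(labels, return_inverse=True)
    return _modularity_adj(graph.adj, labels, resolution, m)


def _one_level(adj, m, gamma, order, tol):
    """Greedy single-node moves until no move improves Q by more than tol.

    Returns (labels, moved) where labels are contiguous community ids.
    """
    n = len(adj)
    com = np.arange(n)
    deg = _degrees(adj)
    sigma_tot = deg.copy().astype(float)
    moved_any = False
    while True:
        n_moves = 0
        for i in order:
            ci = com[i]
            ki = deg[i]
            w_to_com: dict[int, float] = {}
            for j, w in adj[i].items():
                if j != i:
                    cj = com[j]
                    w_to_com[cj] = w_to_com.get(cj, 0.0) + w
            sigma_tot[ci] -= ki
            # gain of inserting i into community c, relative to i isolated
            stay = w_to_com.get(ci, 0.0) / m - gamma * sigma_tot[ci] * ki / (2.0 * m * m)
            best_c, best_gain = ci, stay
            for c, wic in w_to_com.items():
                if c == ci:
                    continue
                gain = wic / m - gamma * sigma_tot[c] * ki / (2.0 * m * m)
                if gain > best_gain + 1e-15 or (abs(gain - best_gain) <= 1e-15 and c < best_c):
                    best_c, best_gain = c, gain
            if best_c != ci and best_gain - stay > tol:
                com[i] = best_c
                n_moves += 1
            sigma_tot[com[i]] += ki
        moved_any = moved_any or n_moves > 0
        if n_moves == 0:
            break
    _, com = np.unique(com, return_inverse=True)
    return com, moved_any


def _aggregate(adj, labels) -> list[dict[int, float]]:
    """Collapse communities into super-nodes; intra-community weight
    (including existing self-loops) becomes the super-node's self-loop."""
    k = int(labels.max()) + 1
    new_adj: list[dict[int, float]] = [dict() for _ in range(k)]
    for i, nbrs in enumerate(adj):
        ci = labels[i]
        for j, w in nbrs.items():
            cj = labels[j]
            if j == i:
                new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
            elif i < j:
                if ci == cj:
                    new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                    new_adj[cj][ci] = new_adj[ci][cj]
    return new_adj


def _louvain_single(graph: WeightedGraph, params: LouvainParams,
                    rng: np.random.Generator) -> Partition:
    m = graph.total_weight
    adj = _to_adj(graph)
    node_labels = np.arange(graph.n_nodes)  # original node -> current super-node
    gamma = params.resolution
    q_trace = [_modularity_adj(adj, np.arange(len(adj)), gamma, m)]

    for _ in range(params.max_passes):
        order = rng.permutation(len(adj))
        level_labels, moved = _one_level(adj, m, gamma, order, params.tolerance)
        node_labels = level_labels[node_labels]
        adj = _aggregate(adj, level_labels)
        q_trace.append(_modularity_adj(adj, np.arange(len(adj)), gamma, m))
        if not moved or len(adj) == 1:
            break

    _, labels = np.unique(node_labels, return_inverse=True)
    return Partition(labels=labels, q=q_trace[-1], subjects=graph.subjects,
                     q_trace=q_trace)


def louvain(graph: WeightedGraph, params: LouvainParams | None = None) -> Partition:
    """Run multi-level Louvain and return the final partition with Q.

    Greedy local moves depend on the node-sweep order, so the optimization
    is repeated for ``n_restarts`` independent seeded orders and the
    highest-modularity run is kept (ties keep the earliest).  Disconnected
    components are handled naturally (singletons stay their own
    communities).  ``params.seed`` fixes all sweep orders, making the output
    deterministic.
    """
    params = params or LouvainParams()
    params.validate()
    if graph.total_weight <= 0:
        raise ValueError("louvain requires a graph with positive total edge weight")
    best = None
    for ss in np.random.SeedSequence(params.seed).spawn(params.n_restarts):
        part = _louvain_single(graph, params, np.random.default_rng(ss))
        if best is None or part.q > best.q + 1e-13:
            best = part
    return best


def relabel_by_size(partition: Partition) -> Partition:
    """Reassign community ids in decreasing size order; equal sizes are
    ordered by their smallest member node.  Idempotent."""
    labels = partition.labels
    sizes = np.bincount(labels)
    first_member = np.full(sizes.size, labels.size)
    for i, c in enumerate(labels):
        if i < first_member[c]:
            first_member[c] = i
    order = sorted(range(sizes.size), key=lambda c: (-sizes[c], first_member[c]))
    remap = np.empty(sizes.size, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return Partition(labels=remap[labels], q=partition.q,
                     subjects=partition.subjects, q_trace=list(partition.q_trace))


def _set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_best_partition(graph: WeightedGraph, resolution: float = 1.0) -> Partition:
    """Globally modularity-optimal partition by enumerating every set
    partition — a cross-check oracle, feasible only for tiny graphs."""
    n = graph.n_nodes
    if n > 10:
        raise ValueError("exhaustive search is only feasible for <= 10 nodes")
    best_q, best_labels = -np.inf, None
    for blocks in _set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for ci, block in enumerate(blocks):
            labels[block] = ci
        q = modularity(graph, labels, resolution)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels
    _, best_labels = np.unique(best_labels, return_inverse=True)
    return Partition(labels=best_labels, q=best_q, subjects=graph.subjects)
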