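"""k-nearest-neighbor graph construction with outlier-arc pruning.

The first stage of the penalized-graph metric: build arcs from every point to
its k nearest neighbors, drop "outlier" arcs (non-reciprocal AND longer than
Q3 + 1.5 IQR of all arc lengths), then symmetrize into an undirected weighted
graph whose connected components are the locally dense structures the second
stage will bridge.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .base_metrics import PairwiseDistances

__all__ = ["ArcSet", "KnnGraph", "build_knn_arcs", "prune_outlier_arcs",
           "symmetrize", "connected_components"]


@dataclass
class ArcSet:
    """Directed arcs i -> j with base-distance weights and reciprocity flags."""

    n: int
    k: int
    source: np.ndarray
    target: np.ndarray
    weight: np.ndarray
    reciprocal: np.ndarray

    def __len__(self) -> int:
        return len(self.source)

    def as_tuples(self):
        return list(zip(self.source.tolist(), self.target.tolist(), self.weight.tolist()))


@dataclass
class KnnGraph:
    """Undirected weighted graph after pruning and symmetrization.

    ``mu`` is the mean edge weight of this graph: the length scale of the
    exponential bridge penalty.  ``mu`` is None for an edgeless graph.
    """

    n: int
    k: int
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_w: np.ndarray
    components: np.ndarray = field(default=None)
    n_components: int = 0
    mu: Optional[float] = None

    def __post_init__(self) -> None:
        if self.components is None:
            self.components, self.n_components = _component_labels(
                self.n, self.edge_i, self.edge_j
            )
        if self.mu is None and len(self.edge_w):
            self.mu = float(np.mean(self.edge_w))

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)

    def edges(self):
        return list(zip(self.edge_i.tolist(), self.edge_j.tolist(), self.edge_w.tolist()))

    def component_sizes(self) -> np.ndarray:
        return np.bincount(self.components, minlength=self.n_components)

    def adjacency(self):
        """Sparse symmetric adjacency (weights) of the undirected edge set."""
        i, j, w = self.edge_i, self.edge_j, self.edge_w
        return coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n),
        ).tocsr()


def _component_labels(n, edge_i, edge_j):
    if len(edge_i) == 0:
        return np.arange(n), n
    adj = coo_matrix((np.ones(len(edge_i)), (edge_i, edge_j)), shape=(n, n))
    n_comp, labels = _cc(adj, directed=False)
    return labels, int(n_comp)


def build_knn_arcs(D: PairwiseDistances, k: int) -> ArcSet:
    """Arcs from every vertex to its k nearest others under ``D``.

    Ties in distance are broken by ascending vertex index (stable argsort),
    so the arc set is deterministic.  The ``reciprocal`` flag marks arcs
    whose reverse is also present.
    """
    d = D.values if isinstance(D, PairwiseDistances) else np.asarray(D, dtype=float)
    n = d.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    order = np.argsort(work, axis=1, kind="stable")[:, :k]
    source = np.repeat(np.arange(n), k)
    target = order.ravel()
    weight = d[source, target]
    has_arc = np.zeros((n, n), dtype=bool)
    has_arc[source, target] = True
    reciprocal = has_arc[target, source]
    return ArcSet(n=n, k=k, source=source, target=target, weight=weight,
                  reciprocal=reciprocal)


def prune_outlier_arcs(arcs: ArcSet) -> ArcSet:
    """Remove arcs that are both non-reciprocal and outlying in length.

    An arc is dropped iff its reverse arc is absent AND its length exceeds
    Q3 + 1.5 IQR of the lengths of *all* arcs (quartiles by linear
    interpolation, computed once before any removal — a single pass).
    Isolated points typically lose their long one-way connection here and
    become singleton components.
    """
    if len(arcs) == 0:
        raise ValueError("empty arc set")
    q1, q3 = np.percentile(arcs.weight, [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    keep = arcs.reciprocal | (arcs.weight <= threshold)
    return ArcSet(n=arcs.n, k=arcs.k, source=arcs.source[keep],
                  target=arcs.target[keep], weight=arcs.weight[keep],
                  reciprocal=arcs.reciprocal[keep])


def symmetrize(arcs: ArcSet) -> KnnGraph:
    """Collapse surviving arcs into an undirected graph.

    An undirected edge (i, j) exists iff at least one of the arcs i->j, j->i
    survived pruning; its weight is the base distance.  Component labels and
    the mean edge weight mu are computed on this edge set.
    """
    if len(arcs) == 0:
        return KnnGraph(n=arcs.n, k=arcs.k, edge_i=np.empty(0, dtype=int),
                        edge_j=np.empty(0, dtype=int), edge_w=np.empty(0))
    lo = np.minimum(arcs.source, arcs.target)
    hi = np.maximum(arcs.source, arcs.target)
    key = lo * arcs.n + hi
    _, first = np.unique(key, return_index=True)
    order = np.sort(first)
    return KnnGraph(n=arcs.n, k=arcs.k, edge_i=lo[order], edge_j=hi[order],
                    edge_w=arcs.weight[order])


def connected_components(g: KnnGraph):
    """Recompute component labels and sizes from the edge list.

    Returns ``(labels, sizes)`` with labels in 0..m-1 ordered by first
    appearance; independent of the labels cached on the graph.
    """
    labels, n_comp = _component_labels(g.n, g.edge_i, g.edge_j)
    sizes = np.bincount(labels, minlength=n_comp)
    return labels, sizes
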