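"""Geodesic (shortest-path) distances and the end-to-end PKNNG metric.

Distances between points are measured as minimum-total-weight paths along the
(possibly augmented) graph: close points are compared by their direct base
distance, distant points by chains of short steps along the manifold, and
points in different subgraphs additionally pay the bridge penalty.  Dijkstra
from every source on the sparse adjacency gives the stated O(n^2 log n).
"""
from __future__ import annotations

from typing import Optional, Union

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path

from .base_metrics import (DataMatrix, PairwiseDistances, correlation_distances,
                           euclidean_distances)
from .knn_graph import KnnGraph, build_knn_arcs, prune_outlier_arcs, symmetrize
from .graph_augmentation import AugmentedGraph, PenaltySpec, connect

__all__ = ["shortest_path_distances", "pknng", "min_k_connected_distances"]


def _edge_arrays(g: Union[KnnGraph, AugmentedGraph]):
    if isinstance(g, AugmentedGraph):
        return g.n, g.all_edges()
    return g.n, (g.edge_i, g.edge_j, g.edge_w)


def shortest_path_distances(g: Union[KnnGraph, AugmentedGraph],
                            allow_disconnected: bool = True) -> PairwiseDistances:
    """All-pairs minimum path weight on the graph (Dijkstra per source).

    Disconnected pairs come back infinite; the result's meta carries a
    ``connected`` flag.  Negative edge weights are rejected.
    """
    n, (i, j, w) = _edge_arrays(g)
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("negative edge weight")
    adj = coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    d = shortest_path(adj, method="D", directed=False)
    connected = bool(np.isfinite(d).all())
    if not connected and not allow_disconnected:
        raise ValueError("graph is disconnected; geodesics are not all finite")
    return PairwiseDistances(d, metric="geodesic", meta={"connected": connected})


def pknng(X=None, *, distances: Optional[PairwiseDistances] = None,
          metric: str = "euclidean", k: int = 5, scheme: str = "minspan",
          penalty: Union[str, PenaltySpec] = "exponential",
          alpha: float = 10.0, k_exp: int = 2) -> PairwiseDistances:
    """The full penalized-knn-graph metric.

    Pipeline: base distances -> knn arcs -> outlier-arc pruning ->
    symmetrize -> components and mean edge weight mu -> penalized bridges
    (with the unpenalized-singleton rule) -> all-pairs geodesics.

    Parameters
    ----------
    X : array-like or DataMatrix, optional
        Data matrix (rows = samples).  Either ``X`` or ``distances`` is given.
    distances : PairwiseDistances, optional
        Precomputed base dissimilarities (skips the base-metric step).
    metric : {"euclidean", "correlation"}
        Base metric when starting from ``X``.
    k : int
        Neighbors for the graph; low values (3-7) follow the manifold without
        shortcuts.  Default 5.
    scheme : {"minspan", "allsubgraphs", "alledges", "medoids"}
    penalty : {"exponential", "linear", "power", "plain"} or PenaltySpec

    Returns
    -------
    PairwiseDistances with metric tag "pknng" and provenance in ``meta``
    (k, scheme, penalty family, mu, component count).
    """
    if (X is None) == (distances is None):
        raise ValueError("provide exactly one of X or distances")
    if distances is None:
        if metric == "euclidean":
            D = euclidean_distances(X)
        elif metric == "correlation":
            D = correlation_distances(X)
        else:
            raise ValueError(f"unknown base metric {metric!r}")
    else:
        D = distances
    spec = penalty if isinstance(penalty, PenaltySpec) else PenaltySpec(
        family=penalty, alpha=alpha, k_exp=k_exp)
    arcs = prune_outlier_arcs(build_knn_arcs(D, k))
    g = symmetrize(arcs)
    aug = connect(g, D, scheme=scheme, spec=spec)
    out = shortest_path_distances(aug, allow_disconnected=False)
    return PairwiseDistances(
        out.values, metric="pknng", sample_ids=D.sample_ids,
        meta={"k": k, "scheme": scheme, "penalty": spec.family, "mu": g.mu,
              "n_components": g.n_components, "base_metric": D.metric,
              "n_bridges": len(aug.bridges)})


def min_k_connected_distances(D: PairwiseDistances):
    """Baseline: geodesics on the smallest-k connected knn-graph.

    Scans k = 1 .. n-1 for the first symmetrized knn-graph (no pruning, no
    bridges) that is connected and returns its unpenalized geodesics together
    with that k (in ``meta["k"]`` as well).
    """
    n = D.n if isinstance(D, PairwiseDistances) else np.asarray(D).shape[0]
    for k in range(1, n):
        g = symmetrize(build_knn_arcs(D, k))
        if g.n_components == 1:
            out = shortest_path_distances(g)
            res = PairwiseDistances(out.values, metric="geodesic",
                                    meta={"k": k, "method": "min-k-connected"})
            return res, k
    raise AssertionError("k = n - 1 always yields a connected graph")
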