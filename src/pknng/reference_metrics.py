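"""Comparison metrics: the minimax path-based metric (PBM) and RBF variants.

PBM defines the length of a path as its *longest* edge and the distance
between two points as the minimum such length over all paths in the complete
base-distance graph — an ultrametric realized on the minimum spanning tree,
with no free parameters.

The RBF metrics transform the base distance through a Gaussian kernel.
RBF-mean fixes the bandwidth sigma at the median pairwise distance; RBF-min
searches a grid of candidates and keeps the sigma whose spectral embedding
gives the most compact clusters (smallest within-cluster sum of squares).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .base_metrics import PairwiseDistances, rbf_distances, sigma_median

__all__ = ["pbm_distances", "spectral_embedding", "sigma_min_select",
           "rbf_mean_distances", "rbf_min_distances", "SigmaSearch"]


def pbm_distances(D: PairwiseDistances) -> PairwiseDistances:
    """Minimax path distance on the complete graph of base distances.

    Kruskal's construction: process pairs by ascending base distance,
    merging groups with union-find; the edge that first joins two groups is
    the bottleneck (minimax) distance for every cross pair, because any path
    between the groups must use an edge at least that long.
    """
    d = np.asarray(D)
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(d[iu, ju], kind="stable")
    out = np.zeros((n, n))
    parent = list(range(n))
    members = [[i] for i in range(n)]

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merged = 0
    for idx in order:
        i, j, w = int(iu[idx]), int(ju[idx]), d[iu[idx], ju[idx]]
        ra, rb = find(i), find(j)
        if ra == rb:
            continue
        if len(members[ra]) < len(members[rb]):
            ra, rb = rb, ra
        a_idx = np.asarray(members[ra])
        b_idx = np.asarray(members[rb])
        out[np.ix_(a_idx, b_idx)] = w
        out[np.ix_(b_idx, a_idx)] = w
        members[ra].extend(members[rb])
        members[rb] = []
        parent[rb] = ra
        merged += 1
        if merged == n - 1:
            break
    ids = D.sample_ids if isinstance(D, PairwiseDistances) else None
    return PairwiseDistances(out, metric="pbm", sample_ids=ids)


@dataclass
class SigmaSearch:
    """Record of an RBF-min bandwidth search."""

    grid: List[float]
    n_clusters: int
    seed: int
    scores: List[float] = field(default_factory=list)
    sigma: Optional[float] = None


def spectral_embedding(D: PairwiseDistances, sigma: float, n_clusters: int,
                       seed: int = 0) -> np.ndarray:
    """Normalized spectral embedding of the Gaussian affinity of ``D``.

    Affinity A = exp(-d^2/sigma^2) with zero diagonal; the top ``n_clusters``
    eigenvectors of D^-1/2 A D^-1/2 are taken and each row rescaled to unit
    length.  Deterministic: eigenvector signs are fixed by making the
    largest-magnitude entry positive (``seed`` is accepted for interface
    symmetry with the clustering step).
    """
    d = np.asarray(D)
    n = d.shape[0]
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not (2 <= n_clusters < n):
        raise ValueError(f"n_clusters must be in [2, {n - 1}], got {n_clusters}")
    A = np.exp(-(d ** 2) / sigma ** 2)
    np.fill_diagonal(A, 0.0)
    rowsum = A.sum(axis=1)
    if (rowsum < 1e-300).any():
        raise ValueError(f"degenerate affinity at sigma={sigma}: some rows are all ~0")
    inv_sqrt = 1.0 / np.sqrt(rowsum)
    M = A * inv_sqrt[:, None] * inv_sqrt[None, :]
    vals, vecs = eigh(M, subset_by_index=(n - n_clusters, n - 1))
    vecs = vecs[:, ::-1]  # descending eigenvalue order
    flip = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    vecs = vecs * flip
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    return vecs / norms[:, None]


def _default_grid(D: PairwiseDistances, size: int = 20) -> np.ndarray:
    med = sigma_median(D)
    return med * np.logspace(-1, 1, size)


def sigma_min_select(D: PairwiseDistances, n_clusters: int,
                     grid=None, seed: int = 0, n_restarts: int = 10):
    """Choose the RBF bandwidth by spectral-projection cluster compactness.

    For each candidate sigma the data are spectrally embedded and clustered
    (seeded k-means, ``n_restarts`` restarts); the sigma with the smallest
    within-cluster sum of squared distances wins, ties going to the smallest
    sigma.  Candidates whose affinity degenerates are skipped.
    """
    if grid is None:
        grid = _default_grid(D)
    grid = sorted(float(s) for s in np.atleast_1d(grid))
    if not grid or any(s <= 0 for s in grid):
        raise ValueError("sigma grid must be nonempty and positive")
    search = SigmaSearch(grid=grid, n_clusters=n_clusters, seed=seed)
    best_sigma, best_score = None, np.inf
    for s in grid:
        try:
            emb = spectral_embedding(D, s, n_clusters, seed=seed)
        except ValueError:
            search.scores.append(float("inf"))
            continue
        km = KMeans(n_clusters=n_clusters, n_init=n_restarts,
                    random_state=seed).fit(emb)
        score = float(km.inertia_)
        search.scores.append(score)
        if score < best_score:  # strict: ties keep the smaller sigma
            best_score, best_sigma = score, s
    if best_sigma is None:
        raise ValueError("every sigma candidate produced a degenerate affinity")
    search.sigma = best_sigma
    return best_sigma, search


def rbf_mean_distances(D: PairwiseDistances) -> PairwiseDistances:
    """RBF distance with sigma fixed at the median pairwise base distance."""
    out = rbf_distances(D, sigma_median(D))
    out.meta["policy"] = "rbf-mean"
    return out


def rbf_min_distances(D: PairwiseDistances, n_clusters: int, grid=None,
                      seed: int = 0) -> PairwiseDistances:
    """RBF distance with sigma chosen by :func:`sigma_min_select`."""
    sigma, search = sigma_min_select(D, n_clusters, grid=grid, seed=seed)
    out = rbf_distances(D, sigma)
    out.meta.update({"policy": "rbf-min", "search_grid": search.grid,
                     "search_scores": search.scores})
    return out
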