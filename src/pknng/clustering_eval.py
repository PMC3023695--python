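"""Clustering adapters, partition-agreement indices and the benchmark harness.

The metric under study only produces dissimilarities; these are handed to two
standard clustering algorithms that accept a precomputed dissimilarity
matrix — PAM (k-medoids, build + swap local search with restarts) and
agglomerative average-linkage hierarchical clustering (with an optional
small-cluster dissolution rule).  Solutions are scored against ground truth
with the corrected Rand index (ARI) and, for the 2-D manifold benchmarks,
clustering accuracy under optimal cluster-to-class matching.

:func:`run_benchmark` repeats generate -> measure -> cluster -> score over
many seeded realizations and reports the raw index values plus boxplot
summaries (quartiles, 1.5 IQR whiskers).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .base_metrics import (DataMatrix, PairwiseDistances, correlation_distances,
                           euclidean_distances)
from .geodesic import min_k_connected_distances, pknng
from .reference_metrics import pbm_distances, rbf_mean_distances, rbf_min_distances

__all__ = [
    "ClusteringResult", "BenchmarkConfig", "BenchmarkReport",
    "cluster_pam", "cluster_hc_average", "corrected_rand",
    "clustering_accuracy", "compute_metric", "run_benchmark",
    "boxplot_summary", "derive_seed",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    method: str
    k: int
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PAM (k-medoids)
# ---------------------------------------------------------------------------

def _pam_build(d: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD initialization: repeatedly add the point whose inclusion
    most reduces the total distance to the nearest medoid."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.minimum(nearest[:, None], d).sum(axis=0)
        gain[medoids] = np.inf
        nxt = int(np.argmin(gain))
        medoids.append(nxt)
        nearest = np.minimum(nearest, d[:, nxt])
    return np.asarray(medoids)


def _pam_swap(d: np.ndarray, medoids: np.ndarray, max_iter: int = 200):
    """Best-improvement swap search; returns (medoids, cost, cost_trace)."""
    n = d.shape[0]
    k = len(medoids)
    medoids = medoids.copy()
    trace = []
    for _ in range(max_iter):
        dm = d[:, medoids]                       # (n, k)
        order = np.argsort(dm, axis=1, kind="stable")
        first = order[:, 0]                      # index (position) of nearest medoid
        dn = dm[np.arange(n), first]
        ds = dm[np.arange(n), order[:, 1]] if k > 1 else dn
        cost = dn.sum()
        trace.append(float(cost))
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        best = (0.0, None, None)
        for pos in range(k):
            base = np.where(first == pos, ds, dn)          # cost if medoid pos removed
            cand_cost = np.minimum(base[:, None], d).sum(axis=0)
            cand_cost[in_medoids] = np.inf
            h = int(np.argmin(cand_cost))
            delta = cand_cost[h] - cost
            if delta < best[0] - 1e-12:
                best = (float(delta), pos, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
    dm = d[:, medoids]
    labels = np.argmin(dm, axis=1)
    return medoids, float(dm[np.arange(n), labels].sum()), trace, labels


def cluster_pam(D: PairwiseDistances, k: int, seed: int = 0,
                n_restarts: int = 10) -> ClusteringResult:
    """PAM k-medoids on a precomputed dissimilarity matrix.

    One deterministic greedy BUILD start plus ``n_restarts - 1`` random
    starts, each refined by best-improvement swaps; the lowest-cost solution
    wins.  Deterministic given ``seed``.
    """
    d = np.asarray(D, dtype=float)
    n = d.shape[0]
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if k == n:
        return ClusteringResult(np.arange(n), "pam", k, seed,
                                {"medoids": np.arange(n), "cost": 0.0})
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        init = _pam_build(d, k) if r == 0 else rng.choice(n, size=k, replace=False)
        medoids, cost, trace, labels = _pam_swap(d, np.asarray(init))
        if best is None or cost < best[1] - 1e-12:
            best = (medoids, cost, trace, labels)
    medoids, cost, trace, labels = best
    return ClusteringResult(labels, "pam", k, seed,
                            {"medoids": medoids, "cost": cost, "cost_trace": trace})


# ---------------------------------------------------------------------------
# hierarchical clustering (average linkage)
# ---------------------------------------------------------------------------

def cluster_hc_average(D: PairwiseDistances, k: int, min_cluster_size: int = 1,
                       dissolved: str = "reassign") -> ClusteringResult:
    """Average-linkage tree cut to ``k`` clusters, with a small-cluster rule.

    With ``min_cluster_size > 1``, clusters below the threshold are
    dissolved: the tree is cut progressively deeper until exactly ``k``
    admissible (large-enough) clusters exist, then each dissolved point is
    reassigned to the admissible cluster with the smallest average
    dissimilarity (``dissolved="reassign"``, default) or excluded with label
    -1 (``dissolved="drop"``).  If no cut yields ``k`` admissible clusters
    the deepest cut with the most admissible clusters is used and the
    shortfall recorded in ``meta``.
    """
    if dissolved not in ("reassign", "drop"):
        raise ValueError("dissolved must be 'reassign' or 'drop'")
    d = np.asarray(D, dtype=float)
    n = d.shape[0]
    if not (2 <= k < n):
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")
    Z = linkage(squareform(d, checks=False), method="average")
    best_labels, best_admissible = None, -1
    for kk in range(k, n + 1):
        raw = fcluster(Z, t=kk, criterion="maxclust") - 1
        counts = np.bincount(raw)
        admissible = np.flatnonzero(counts >= min_cluster_size)
        if len(admissible) > best_admissible and len(admissible) <= k:
            best_labels, best_admissible = raw, len(admissible)
        if len(admissible) == k:
            best_labels, best_admissible = raw, k
            break
    raw = best_labels
    counts = np.bincount(raw)
    admissible = np.flatnonzero(counts >= min_cluster_size)
    labels = np.full(n, -1, dtype=int)
    remap = {int(c): i for i, c in enumerate(admissible)}
    for c, i in remap.items():
        labels[raw == c] = i
    n_dissolved = int((labels == -1).sum())
    if n_dissolved and dissolved == "reassign":
        for x in np.flatnonzero(labels == -1):
            means = [d[x, labels == i].mean() for i in range(len(admissible))]
            labels[x] = int(np.argmin(means))
    return ClusteringResult(labels, "hc-average", k, None,
                            {"min_cluster_size": min_cluster_size,
                             "n_dissolved_points": n_dissolved,
                             "n_clusters_found": int(best_admissible),
                             "dissolved": dissolved})


# ---------------------------------------------------------------------------
# agreement indices
# ---------------------------------------------------------------------------

def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table


def corrected_rand(a, b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    From the contingency table n_ij: (sum C(n_ij,2) - E) / (M - E) with
    E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2) and
    M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.  1 iff the partitions are
    identical up to relabeling; ~0 in expectation for independent labelings.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = len(a)
    table = _contingency(a, b)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-one-cluster etc.)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def clustering_accuracy(pred, truth) -> float:
    """Percentage of points correctly assigned under the best one-to-one
    matching of predicted clusters to true classes (Hungarian algorithm).

    Points with predicted label -1 (dropped by the small-cluster rule) count
    as misassigned.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    keep = pred >= 0
    table = _contingency(pred[keep], truth[keep])
    rows, cols = linear_sum_assignment(-table)
    return 100.0 * table[rows, cols].sum() / len(pred)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def derive_seed(master: int, rep: int) -> int:
    """Deterministic per-realization seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master), int(rep)]).generate_state(1)[0]
               % 2**31)


def boxplot_summary(values) -> dict:
    """Median, quartiles and 1.5 IQR whiskers (lowest/highest datum within)."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
            "mean": float(v.mean()), "n": int(len(v))}


def _base_distances(X: DataMatrix, base: str) -> PairwiseDistances:
    if base == "euclidean":
        return euclidean_distances(X)
    if base == "correlation":
        return correlation_distances(X)
    raise ValueError(f"unknown base metric {base!r}")


def compute_metric(X: DataMatrix, spec: dict, n_clusters: int,
                   seed: int = 0) -> PairwiseDistances:
    """Compute one named metric from a data matrix.

    ``spec`` is a dict with at least ``name`` in {euclidean, correlation,
    pknng, pbm, rbf-mean, rbf-min, min-k}; pknng additionally honors
    ``base``, ``k``, ``scheme``, ``penalty``; pbm/rbf/min-k honor ``base``.
    """
    name = spec["name"]
    base = spec.get("base", "euclidean")
    if name in ("euclidean", "correlation"):
        return _base_distances(X, name)
    D = _base_distances(X, base)
    if name == "pknng":
        return pknng(distances=D, k=spec.get("k", 5),
                     scheme=spec.get("scheme", "minspan"),
                     penalty=spec.get("penalty", "exponential"))
    if name == "pbm":
        return pbm_distances(D)
    if name == "rbf-mean":
        return rbf_mean_distances(D)
    if name == "rbf-min":
        return rbf_min_distances(D, n_clusters, seed=seed)
    if name == "min-k":
        return min_k_connected_distances(D)[0]
    raise ValueError(f"unknown metric {name!r}")


def metric_label(spec: dict) -> str:
    if "label" in spec:
        return spec["label"]
    name = spec["name"]
    if name == "pknng":
        return (f"pknng({spec.get('base', 'euclidean')},{spec.get('scheme', 'minspan')},"
                f"{spec.get('penalty', 'exponential')},k={spec.get('k', 5)})")
    if name in ("pbm", "rbf-mean", "rbf-min", "min-k"):
        return f"{name}({spec.get('base', 'euclidean')})"
    return name


@dataclass
class BenchmarkConfig:
    """Fully materialized configuration of a repeated-realization benchmark."""

    metrics: List[dict]
    methods: List[str]
    n_clusters: int
    generator: Optional[str] = None
    generator_params: dict = field(default_factory=dict)
    data: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    reps: int = 100
    subsample_fraction: float = 1.0
    seed: int = 0
    min_cluster_size: int = 1
    compute_accuracy: bool = False

    def __post_init__(self):
        if (self.generator is None) == (self.data is None):
            raise ValueError("provide exactly one of generator or data")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.data is not None and self.labels is None:
            raise ValueError("fixed data requires ground-truth labels")
        for m in self.methods:
            if m not in ("pam", "hc-average"):
                raise ValueError(f"unknown clustering method {m!r}")

    def echo(self) -> dict:
        out = asdict(self)
        out.pop("data")
        out.pop("labels")
        out["uses_fixed_data"] = self.data is not None
        return out


@dataclass
class BenchmarkReport:
    """Raw per-realization index values plus boxplot summaries."""

    config: dict
    crand: Dict[str, List[float]]
    accuracy: Dict[str, List[float]]
    failures: List[dict]

    def summaries(self, which: str = "crand") -> Dict[str, dict]:
        raw = self.crand if which == "crand" else self.accuracy
        return {key: boxplot_summary(vals) for key, vals in raw.items() if vals}

    def mean(self, metric_key: str, which: str = "crand") -> float:
        raw = self.crand if which == "crand" else self.accuracy
        return float(np.mean(raw[metric_key]))

    def to_dict(self) -> dict:
        return {"config": self.config,
                "crand": self.crand,
                "accuracy": self.accuracy,
                "crand_summary": self.summaries("crand"),
                "accuracy_summary": self.summaries("accuracy"),
                "failures": self.failures}


def _realize(cfg: BenchmarkConfig, rep_seed: int):
    from .synthetic_data import generate
    if cfg.generator is not None:
        ds = generate(cfg.generator, seed=rep_seed, **cfg.generator_params)
        X, truth = ds.X, ds.labels
    else:
        X, truth = cfg.data, np.asarray(cfg.labels)
    if cfg.subsample_fraction < 1.0:
        rng = np.random.default_rng(rep_seed)
        m = int(np.floor(cfg.subsample_fraction * X.shape[0]))
        idx = np.sort(rng.choice(X.shape[0], size=m, replace=False))
        X, truth = X[idx], truth[idx]
    return DataMatrix(X), truth


def run_benchmark(cfg: BenchmarkConfig, progress=None) -> BenchmarkReport:
    """Repeat generate/subsample -> metric -> cluster -> score over ``reps``.

    Per-realization seeds derive deterministically from the master seed, so
    the whole report is reproducible.  Failures of any stage are recorded
    per (realization, metric) without aborting the run.
    """
    crand: Dict[str, List[float]] = {}
    acc: Dict[str, List[float]] = {}
    failures: List[dict] = []
    for r in range(cfg.reps):
        rep_seed = derive_seed(cfg.seed, r)
        X, truth = _realize(cfg, rep_seed)
        for mspec in cfg.metrics:
            label = metric_label(mspec)
            try:
                D = compute_metric(X, mspec, cfg.n_clusters, seed=rep_seed)
            except Exception as exc:  # recorded, not fatal
                failures.append({"rep": r, "metric": label, "stage": "metric",
                                 "error": str(exc)})
                continue
            for method in cfg.methods:
                key = f"{label}|{method}"
                try:
                    if method == "pam":
                        res = cluster_pam(D, cfg.n_clusters, seed=rep_seed)
                    else:
                        res = cluster_hc_average(D, cfg.n_clusters,
                                                 min_cluster_size=cfg.min_cluster_size)
                except Exception as exc:
                    failures.append({"rep": r, "metric": label, "stage": method,
                                     "error": str(exc)})
                    continue
                crand.setdefault(key, []).append(corrected_rand(res.labels, truth))
                if cfg.compute_accuracy:
                    acc.setdefault(key, []).append(
                        clustering_accuracy(res.labels, truth))
        if progress is not None:
            progress(r)
    return BenchmarkReport(config=cfg.echo(), crand=crand, accuracy=acc,
                           failures=failures)
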