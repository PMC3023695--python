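"""Bridging disconnected subgraphs with penalized edges.

The second stage of the metric: the knn-graph usually splits into several
components (ideally one or more per cluster).  Bridging edges reconnect them
so geodesics exist between every pair, but carry a penalized weight so that
paths crossing low-density regions are clearly more expensive than paths that
stay on the manifold.  Four connection schemes are provided:

* ``minspan``      — minimum spanning set over components (m - 1 bridges),
* ``allsubgraphs`` — closest cross pair for every component pair,
* ``alledges``     — every missing vertex pair becomes a (penalized) edge,
* ``medoids``      — bridges between component medoids only.

Bridges that touch a singleton component (an isolated outlier point) keep
their unpenalized base length, so clustering later absorbs outliers into the
nearest cluster instead of splitting them off.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .base_metrics import PairwiseDistances
from .knn_graph import KnnGraph, _component_labels

__all__ = [
    "PenaltySpec", "Bridge", "AugmentedGraph", "penalty_weight",
    "connect_minspan", "connect_all_subgraphs", "connect_all_edges",
    "connect_medoids", "apply_singleton_rule", "connect",
]

SCHEMES = ("minspan", "allsubgraphs", "alledges", "medoids")


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family for bridge weights.

    exponential : w = d * exp(d / mu)      (the default; mu = mean edge weight)
    power       : w = d * (d / mu)^k_exp
    linear      : w = alpha * d
    plain       : w = d                    (no penalization; ablation baseline)
    """

    family: str = "exponential"
    alpha: float = 10.0
    k_exp: int = 2

    def __post_init__(self):
        if self.family not in ("exponential", "linear", "power", "plain"):
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.family == "linear" and self.alpha <= 0:
            raise ValueError("linear penalty needs alpha > 0")
        if self.family == "power" and self.k_exp < 1:
            raise ValueError("power penalty needs integer exponent >= 1")


@dataclass(frozen=True)
class Bridge:
    i: int
    j: int
    base: float       # base distance between the endpoints
    weight: float     # penalized (or unpenalized-singleton) graph weight
    provenance: str   # "bridge" | "singleton_bridge"


@dataclass
class AugmentedGraph:
    """A KnnGraph plus the bridging edges that make it connected."""

    graph: KnnGraph
    bridges: List[Bridge]
    scheme: str
    penalty: PenaltySpec
    components: np.ndarray = field(default=None)   # labels of the *input* graph
    n_components: int = 0

    @property
    def n(self) -> int:
        return self.graph.n

    def all_edges(self):
        """(i, j, weight) arrays over original edges plus bridges."""
        bi = np.array([b.i for b in self.bridges], dtype=int)
        bj = np.array([b.j for b in self.bridges], dtype=int)
        bw = np.array([b.weight for b in self.bridges], dtype=float)
        return (np.concatenate([self.graph.edge_i, bi]),
                np.concatenate([self.graph.edge_j, bj]),
                np.concatenate([self.graph.edge_w, bw]))

    def is_connected(self) -> bool:
        i, j, _ = self.all_edges()
        _, n_comp = _component_labels(self.n, i, j)
        return n_comp == 1


def penalty_weight(d, mu: float, spec: PenaltySpec = PenaltySpec()):
    """Penalized weight of a bridge of base length ``d`` at scale ``mu``.

    Vectorized over ``d``.  The exponential form keeps bridges on the order
    of mu cheap (factor ~e) while bridges across real cluster gaps explode.
    """
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    d = np.asarray(d, dtype=float)
    if spec.family == "exponential":
        # exponent capped so extreme bridges stay finite (ordering unaffected)
        w = d * np.exp(np.minimum(d / mu, 500.0))
    elif spec.family == "linear":
        w = spec.alpha * d
    elif spec.family == "power":
        w = d * (d / mu) ** spec.k_exp
    else:  # plain
        w = d.copy() if d.ndim else d
    return float(w) if np.ndim(w) == 0 else w


def _require_mu(g: KnnGraph, spec: PenaltySpec) -> float:
    if spec.family in ("exponential", "power"):
        if g.mu is None or g.mu <= 0:
            raise ValueError("graph has no positive mean edge weight; "
                             "cannot scale the penalty")
        return g.mu
    return g.mu if (g.mu and g.mu > 0) else 1.0


def _closest_cross_pairs(D: np.ndarray, comp: np.ndarray, m: int):
    """For each component pair (a < b): the closest cross pair and its distance.

    Ties are resolved lexicographically on the global vertex pair (i, j): the
    argmin scans members in ascending index order.
    """
    members = [np.flatnonzero(comp == c) for c in range(m)]
    cost = np.full((m, m), np.inf)
    pair = {}
    for a in range(m):
        for b in range(a + 1, m):
            sub = D[np.ix_(members[a], members[b])]
            flat = int(np.argmin(sub))
            r, c = divmod(flat, sub.shape[1])
            i, j = int(members[a][r]), int(members[b][c])
            cost[a, b] = cost[b, a] = sub[r, c]
            pair[(a, b)] = (min(i, j), max(i, j))
    return cost, pair, members


def apply_singleton_rule(bridges: List[Bridge], component_sizes: np.ndarray,
                         components: np.ndarray) -> List[Bridge]:
    """Leave bridges that touch a singleton component unpenalized.

    An isolated point carries no density information; penalizing its only
    connection would turn every outlier into its own cluster.  Instead the
    bridge keeps the plain base distance so the outlier attaches to the
    nearest structure.
    """
    out = []
    for b in bridges:
        if component_sizes[components[b.i]] == 1 or component_sizes[components[b.j]] == 1:
            out.append(Bridge(b.i, b.j, b.base, b.base, "singleton_bridge"))
        else:
            out.append(b)
    return out


def _finalize(g, raw, scheme, spec, comp, m):
    sizes = np.bincount(comp, minlength=m)
    bridges = apply_singleton_rule(raw, sizes, comp)
    aug = AugmentedGraph(graph=g, bridges=bridges, scheme=scheme, penalty=spec,
                         components=comp, n_components=m)
    return aug


def _penalized(i, j, d, mu, spec) -> Bridge:
    return Bridge(int(i), int(j), float(d), float(penalty_weight(d, mu, spec)), "bridge")


def connect_minspan(g: KnnGraph, D: PairwiseDistances,
                    spec: PenaltySpec = PenaltySpec()) -> AugmentedGraph:
    """Minimum spanning set: m - 1 shortest bridges that connect all components.

    The component graph (cost = shortest cross-pair distance) is spanned by
    its minimum spanning tree; each tree edge becomes a bridge at the
    realizing closest pair of points.
    """
    d = np.asarray(D)
    comp, m = g.components, g.n_components
    mu = _require_mu(g, spec)
    if m == 1:
        return _finalize(g, [], "minspan", spec, comp, m)
    cost, pair, _ = _closest_cross_pairs(d, comp, m)
    # +1 shift keeps zero-cost pairs representable in the sparse MST input;
    # a constant shift of every edge leaves the spanning tree unchanged.
    rows, cols = zip(*pair.keys())
    data = [cost[a, b] + 1.0 for a, b in pair.keys()]
    mst = minimum_spanning_tree(coo_matrix((data, (rows, cols)), shape=(m, m))).tocoo()
    raw = []
    for a, b in zip(mst.row, mst.col):
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        i, j = pair[(a, b)]
        raw.append(_penalized(i, j, d[i, j], mu, spec))
    raw.sort(key=lambda t: (t.i, t.j))
    return _finalize(g, raw, "minspan", spec, comp, m)


def connect_all_subgraphs(g: KnnGraph, D: PairwiseDistances,
                          spec: PenaltySpec = PenaltySpec()) -> AugmentedGraph:
    """One bridge per component pair, each at the closest cross pair.

    This superset of the MinSpan bridges (m(m-1)/2 of them) adds redundancy
    against the one-dimensional instability of a pure spanning set.
    """
    d = np.asarray(D)
    comp, m = g.components, g.n_components
    mu = _require_mu(g, spec)
    raw = []
    if m > 1:
        _, pair, _ = _closest_cross_pairs(d, comp, m)
        for (a, b), (i, j) in sorted(pair.items()):
            raw.append(_penalized(i, j, d[i, j], mu, spec))
        raw.sort(key=lambda t: (t.i, t.j))
    return _finalize(g, raw, "allsubgraphs", spec, comp, m)


def connect_all_edges(g: KnnGraph, D: PairwiseDistances,
                      spec: PenaltySpec = PenaltySpec()) -> AugmentedGraph:
    """Add every missing vertex pair as a penalized bridge (complete graph).

    With the plain penalty this reduces the geodesic metric to the base
    metric itself, which is the natural ablation baseline.
    """
    d = np.asarray(D)
    comp, m = g.components, g.n_components
    mu = _require_mu(g, spec)
    n = g.n
    present = np.zeros((n, n), dtype=bool)
    present[g.edge_i, g.edge_j] = True
    iu, ju = np.triu_indices(n, k=1)
    missing = ~present[iu, ju]
    raw = [_penalized(i, j, d[i, j], mu, spec)
           for i, j in zip(iu[missing], ju[missing])]
    return _finalize(g, raw, "alledges", spec, comp, m)


def connect_medoids(g: KnnGraph, D: PairwiseDistances,
                    spec: PenaltySpec = PenaltySpec()) -> AugmentedGraph:
    """Bridges between the medoids of every component pair.

    The medoid of a component is its member minimizing the summed base
    distance to the other members (ties -> lowest index).  Because the
    medoid bridges ignore the closest cross pairs, this scheme cannot follow
    a curved manifold; it exists as a deliberately naive comparator.
    """
    d = np.asarray(D)
    comp, m = g.components, g.n_components
    mu = _require_mu(g, spec)
    raw = []
    if m > 1:
        medoids = []
        for c in range(m):
            idx = np.flatnonzero(comp == c)
            sums = d[np.ix_(idx, idx)].sum(axis=1)
            medoids.append(int(idx[int(np.argmin(sums))]))
        for a in range(m):
            for b in range(a + 1, m):
                i, j = sorted((medoids[a], medoids[b]))
                raw.append(_penalized(i, j, d[i, j], mu, spec))
        raw.sort(key=lambda t: (t.i, t.j))
    return _finalize(g, raw, "medoids", spec, comp, m)


_CONNECTORS = {
    "minspan": connect_minspan,
    "allsubgraphs": connect_all_subgraphs,
    "alledges": connect_all_edges,
    "medoids": connect_medoids,
}


def connect(g: KnnGraph, D: PairwiseDistances, scheme: str = "minspan",
            spec: PenaltySpec = PenaltySpec()) -> AugmentedGraph:
    """Dispatch to a connection scheme by name."""
    try:
        fn = _CONNECTORS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}") from None
    return fn(g, D, spec)
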