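import numpy as np
import pytest

from pknng import PairwiseDistances, euclidean_distances


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_points(rng):
    """8 random 2-D points with generic (tie-free) pairwise distances."""
    return rng.normal(size=(8, 2))


@pytest.fixture
def random_distances(random_points):
    return euclidean_distances(random_points)


def floyd_warshall_oracle(n, edges):
    """Triple-loop Floyd-Warshall on an undirected weighted edge list."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j, w in edges:
        d[i, j] = min(d[i, j], w)
        d[j, i] = min(d[j, i], w)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def flood_fill_components(n, edges):
    """BFS component labels, independent of any library routine."""
    adj = {i: [] for i in range(n)}
    for i, j, *_ in edges:
        adj[i].append(j)
        adj[j].append(i)
    labels = [-1] * n
    comp = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = comp
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if labels[w] == -1:
                    labels[w] = comp
                    stack.append(w)
        comp += 1
    return np.array(labels), comp


def random_connected_graph(rng, n, extra_edges=None):
    """Random connected weighted graph: a random spanning tree plus extras."""
    order = rng.permutation(n)
    edges = []
    for idx in range(1, n):
        j = order[idx]
        i = order[rng.integers(0, idx)]
        edges.append((int(min(i, j)), int(max(i, j)), float(rng.uniform(0.1, 5.0))))
    if extra_edges is None:
        extra_edges = int(rng.integers(0, n))
    seen = {(i, j) for i, j, _ in edges}
    for _ in range(extra_edges):
        i, j = rng.integers(0, n, size=2)
        i, j = int(min(i, j)), int(max(i, j))
        if i != j and (i, j) not in seen:
            seen.add((i, j))
            edges.append((i, j, float(rng.uniform(0.1, 5.0))))
    return edges


def make_distances(matrix):
    return PairwiseDistances(np.asarray(matrix, dtype=float))
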