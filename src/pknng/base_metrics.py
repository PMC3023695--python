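"""Base dissimilarities: Euclidean, Pearson correlation and the RBF-kernel distance.

These are the "stage one" measures every downstream graph construction starts
from.  All distance outputs share one container, :class:`PairwiseDistances`,
which enforces the invariants the rest of the pipeline relies on (symmetry,
exact-zero diagonal, nonnegativity).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DataMatrix",
    "PairwiseDistances",
    "euclidean_distances",
    "correlation_distances",
    "rbf_distances",
    "sigma_median",
]


@dataclass
class DataMatrix:
    """An n x p numeric matrix: rows are samples, columns are features (genes).

    Parameters
    ----------
    values : ndarray of shape (n, p)
        The expression (or coordinate) matrix.  Must be finite.
    sample_ids : sequence of str, optional
        Row identifiers; defaults to ``s0 .. s{n-1}``.
    labels : ndarray of int, optional
        Ground-truth class per row, used only for evaluation.
    """

    values: np.ndarray
    sample_ids: Optional[Sequence[str]] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix requires a 2-D array")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need at least 2 samples and 1 feature, got {n} x {p}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            row = int(np.nonzero(bad.any(axis=1))[0][0])
            raise ValueError(f"non-finite value in row {row}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        else:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length does not match row count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class PairwiseDistances:
    """A symmetric n x n dissimilarity matrix with an exact-zero diagonal."""

    values: np.ndarray
    metric: str = "euclidean"
    sample_ids: Optional[Sequence[str]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        finite = np.isfinite(d)
        if not np.array_equal(d[finite], np.abs(d[finite])):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(d, d.T, rtol=1e-8, atol=1e-8, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        d = 0.5 * (d + d.T)  # kill last-bit asymmetry so downstream code is exact
        np.fill_diagonal(d, 0.0)
        self.values = d
        if self.sample_ids is not None:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != d.shape[0]:
                raise ValueError("sample_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def _as_values(X) -> np.ndarray:
    if isinstance(X, DataMatrix):
        return X.values
    return DataMatrix(np.asarray(X, dtype=float)).values


def _ids(X) -> Optional[Sequence[str]]:
    return X.sample_ids if isinstance(X, DataMatrix) else None


def euclidean_distances(X) -> PairwiseDistances:
    """All-pairs L2 distances between the rows of ``X``."""
    v = _as_values(X)
    d = squareform(pdist(v, metric="euclidean"))
    return PairwiseDistances(d, metric="euclidean", sample_ids=_ids(X))


def correlation_distances(X) -> PairwiseDistances:
    """Pearson-correlation dissimilarity between rows: d = 1 - r, in [0, 2].

    Each row needs nonzero variance for r to exist; constant rows are rejected.
    """
    v = _as_values(X)
    sd = v.std(axis=1)
    if (sd == 0).any():
        row = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"row {row} is constant; Pearson correlation undefined")
    d = squareform(pdist(v, metric="correlation"))  # pdist correlation is 1 - r
    d = np.clip(d, 0.0, 2.0)
    return PairwiseDistances(d, metric="correlation", sample_ids=_ids(X))


def rbf_distances(D: PairwiseDistances, sigma: float) -> PairwiseDistances:
    """Distance induced by the Gaussian kernel K = exp(-d^2 / sigma^2).

    In the kernel feature space ||phi(x) - phi(z)||^2 = 2 - 2 K(x, z), so the
    induced distance is sqrt(2 - 2 exp(-d^2/sigma^2)): a strictly increasing,
    bounded (< sqrt(2)) transform of the base distance.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    d = D.values if isinstance(D, PairwiseDistances) else np.asarray(D, dtype=float)
    out = np.sqrt(np.clip(2.0 - 2.0 * np.exp(-(d ** 2) / sigma ** 2), 0.0, None))
    ids = D.sample_ids if isinstance(D, PairwiseDistances) else None
    return PairwiseDistances(out, metric="rbf", sample_ids=ids, meta={"sigma": float(sigma)})


def sigma_median(D: PairwiseDistances) -> float:
    """Median of the n(n-1)/2 off-diagonal distances (the RBF-mean sigma).

    Even counts take the arithmetic mean of the two central order statistics.
    """
    d = D.values if isinstance(D, PairwiseDistances) else np.asarray(D, dtype=float)
    upper = d[np.triu_indices(d.shape[0], k=1)]
    if np.all(upper == 0):
        raise ValueError("all pairwise distances are zero; sigma is degenerate")
    return float(np.median(upper))
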