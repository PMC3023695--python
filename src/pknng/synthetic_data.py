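"""Synthetic benchmark generators.

Two families of controlled clustering problems:

* Simulated-microarray datasets A-1 .. A-5: Gaussian clusters in a
  high-dimensional "gene" space.  A-1 has three spherical clusters built from
  ten 30-gene blocks whose common mean is drawn from {-0.5, 0, +0.5}; A-2 to
  A-5 are *elongated* clusters whose principal axis carries 10% of the total
  standard deviation, the remainder spread equally over the other axes, with
  center separations measured in units of the principal-axis SD.  A-5 appends
  200 pure-noise genes.

* Low-dimensional manifold problems — two-moons (2 clusters), three-spirals
  (3), three-rings (5, the two outer rings split in halves) — each available
  in four embeddings: the native 2-D plane, a 3-D swiss-roll coiling of that
  plane, the swiss-roll plus Gaussian noise, and a 10-D version (7 zero
  dimensions appended, a Haar-random rotation, then Gaussian noise in all 10).

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .base_metrics import DataMatrix

__all__ = [
    "LabeledDataset", "ElongatedSpec",
    "gen_a1", "gen_a2", "gen_a3", "gen_a4", "gen_a5", "gen_elongated",
    "gen_two_moons", "gen_three_spirals", "gen_three_rings",
    "embed_swiss_roll", "add_embedding_noise", "embed_10d",
    "make_manifold_dataset", "generate",
]

# total-SD budget for the elongated clusters: fixes the principal SD at
# principal_fraction * SD_BUDGET (=1 for the 10% problems) so that center
# separations are in natural units; absolute scale cancels in clustering.
SD_BUDGET = 10.0

NOISE_PRESETS = {
    "moons": {"low": 0.05, "medium": 0.10, "high": 0.15},      # radial sd, radius 1
    "spirals": {"low": 0.02, "medium": 0.04, "high": 0.06},    # sd per unit radius
    "rings": {"low": 0.02, "medium": 0.04, "high": 0.06},      # radial sd
}
EMBED_NOISE_FRACTION = 0.01   # embedding noise sd as a fraction of data range
SWISS_ROLL_INTERVAL = (1.5 * np.pi, 3.4 * np.pi)


@dataclass
class LabeledDataset:
    """A generated dataset with its ground-truth cluster labels."""

    X: np.ndarray
    labels: np.ndarray
    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length does not match row count")

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))

    def data_matrix(self) -> DataMatrix:
        return DataMatrix(self.X, labels=self.labels)


# ---------------------------------------------------------------------------
# simulated-microarray problems
# ---------------------------------------------------------------------------

def gen_a1(seed: int) -> LabeledDataset:
    """Three spherical clusters of 50 samples in a 300-gene space.

    The genes form 10 blocks of 30.  Within each (block, cluster) cell every
    sample is drawn N(alpha * 1, I) with a common alpha picked uniformly from
    {-0.5, 0, +0.5}: blocks model co-regulated gene sets commonly up- or
    down-regulated per condition.
    """
    rng = np.random.default_rng(seed)
    n_clusters, per_cluster, blocks, block_width = 3, 50, 10, 30
    X = np.empty((n_clusters * per_cluster, blocks * block_width))
    alphas = np.empty((n_clusters, blocks))
    for c in range(n_clusters):
        rows = slice(c * per_cluster, (c + 1) * per_cluster)
        for b in range(blocks):
            alpha = rng.choice([-0.5, 0.0, 0.5])
            alphas[c, b] = alpha
            cols = slice(b * block_width, (b + 1) * block_width)
            X[rows, cols] = rng.normal(alpha, 1.0, size=(per_cluster, block_width))
    labels = np.repeat(np.arange(n_clusters), per_cluster)
    return LabeledDataset(X, labels, "a1", seed, {"alphas": alphas})


@dataclass(frozen=True)
class ElongatedSpec:
    """Parameters of an elongated-Gaussian-clusters problem.

    ``principal_fraction`` of the total SD budget goes to the (random)
    principal axis; the rest is split equally over the other p-1 axes.
    ``separation_multiple`` is the gap between consecutive cluster centers in
    units of the principal-axis SD.  With ``axes="parallel"`` all clusters
    share one principal axis and the centers are offset *orthogonally* to it
    (parallel elongated clusters side by side); with ``axes="independent"``
    each cluster gets its own random axis and centers lie along an
    independent random direction.
    """

    n_clusters: int
    samples_per_cluster: int = 25
    p: int = 100
    principal_fraction: float = 0.1
    separation_multiple: float = 1.5
    axes: str = "parallel"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.principal_fraction < 1.0:
            raise ValueError("principal_fraction must lie in (0, 1)")
        if self.separation_multiple <= 0:
            raise ValueError("separation_multiple must be positive")
        if self.axes not in ("parallel", "independent"):
            raise ValueError(f"axes must be 'parallel' or 'independent', got {self.axes!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _basis_with_first_axis(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal basis (columns) whose first column is the unit vector u."""
    p = len(u)
    G = rng.standard_normal((p, p))
    G[:, 0] = u
    Q, _ = np.linalg.qr(G)
    if np.dot(Q[:, 0], u) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def gen_elongated(spec: ElongatedSpec) -> LabeledDataset:
    """Elongated Gaussian clusters (the A-2/A-3/A-4 construction)."""
    rng = np.random.default_rng(spec.seed)
    p, m = spec.p, spec.n_clusters
    principal_sd = spec.principal_fraction * SD_BUDGET
    other_sd = (1.0 - spec.principal_fraction) * SD_BUDGET / (p - 1)
    sds = np.full(p, other_sd)
    sds[0] = principal_sd

    if spec.axes == "parallel":
        shared_u = _unit(rng.standard_normal(p))
        # center offsets orthogonal to the shared axis: parallel cigars
        v = rng.standard_normal(p)
        v = _unit(v - np.dot(v, shared_u) * shared_u)
    else:
        shared_u = None
        v = _unit(rng.standard_normal(p))

    gap = spec.separation_multiple * principal_sd
    blocks = []
    axes_used = []
    for c in range(m):
        u = shared_u if shared_u is not None else _unit(rng.standard_normal(p))
        axes_used.append(u)
        Q = _basis_with_first_axis(u, rng)
        g = rng.standard_normal((spec.samples_per_cluster, p))
        blocks.append(c * gap * v + (g * sds) @ Q.T)
    X = np.vstack(blocks)
    labels = np.repeat(np.arange(m), spec.samples_per_cluster)
    return LabeledDataset(
        X, labels, "elongated", spec.seed,
        {"spec": spec, "principal_sd": principal_sd, "other_sd": other_sd,
         "axes": np.array(axes_used), "offset_direction": v})


def gen_a2(seed: int) -> LabeledDataset:
    """Two parallel elongated clusters (25 x 100), axes 1.5 principal-SD apart."""
    ds = gen_elongated(ElongatedSpec(2, 25, 100, 0.1, 1.5, "parallel", seed))
    return LabeledDataset(ds.X, ds.labels, "a2", seed, ds.params)


def gen_a3(seed: int) -> LabeledDataset:
    """Two elongated clusters with independent random axes, separated by 2 SD."""
    ds = gen_elongated(ElongatedSpec(2, 25, 100, 0.1, 2.0, "independent", seed))
    return LabeledDataset(ds.X, ds.labels, "a3", seed, ds.params)


def gen_a4(seed: int) -> LabeledDataset:
    """Three elongated clusters with independent axes, neighbors 1 SD apart."""
    ds = gen_elongated(ElongatedSpec(3, 25, 100, 0.1, 1.0, "independent", seed))
    return LabeledDataset(ds.X, ds.labels, "a4", seed, ds.params)


def gen_a5(seed: int) -> LabeledDataset:
    """A-4-style clusters over 200 informative genes plus 200 pure-noise genes.

    The noise genes are centered Gaussians with the same SD as the
    non-principal directions; dropping them recovers the informative block
    exactly (same seed, same values).
    """
    informative = gen_elongated(ElongatedSpec(3, 25, 200, 0.1, 1.0, "independent", seed))
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A5]))
    other_sd = informative.params["other_sd"]
    noise = noise_rng.normal(0.0, other_sd, size=(informative.X.shape[0], 200))
    X = np.hstack([informative.X, noise])
    return LabeledDataset(X, informative.labels, "a5", seed,
                          {**informative.params, "n_noise_genes": 200})


# ---------------------------------------------------------------------------
# 2-D manifold problems
# ---------------------------------------------------------------------------

def _noise_amplitude(problem: str, noise_level: str, amplitude: Optional[float]):
    if amplitude is not None:
        return float(amplitude)
    try:
        return NOISE_PRESETS[problem][noise_level]
    except KeyError:
        raise ValueError(
            f"noise_level must be one of {list(NOISE_PRESETS[problem])}, "
            f"got {noise_level!r}") from None


def gen_two_moons(n: int = 100, noise_level: str = "low", seed: int = 0,
                  amplitude: Optional[float] = None) -> LabeledDataset:
    """Two interleaved arcs of circumference with radial Gaussian noise.

    ``n`` points per arc, angles uniform on [0, pi]; noise perturbs the
    radius (fixed amplitude).  ``amplitude`` overrides the preset.
    """
    if n < 10:
        raise ValueError("need at least 10 points per cluster")
    sd = _noise_amplitude("moons", noise_level, amplitude)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, np.pi, size=2 * n)
    r = 1.0 + rng.normal(0.0, sd, size=2 * n)
    up = np.column_stack([r[:n] * np.cos(theta[:n]), r[:n] * np.sin(theta[:n])])
    down = np.column_stack([1.0 - r[n:] * np.cos(theta[n:]),
                            0.5 - r[n:] * np.sin(theta[n:])])
    X = np.vstack([up, down])
    labels = np.repeat([0, 1], n)
    return LabeledDataset(X, labels, "moons", seed,
                          {"noise_level": noise_level, "sd": sd, "n_per_cluster": n})


def gen_three_spirals(n: int = 100, noise_level: str = "low", seed: int = 0,
                      amplitude: Optional[float] = None) -> LabeledDataset:
    """Three equally separated spirals with radius-proportional radial noise.

    Each arm is the Archimedean curve radius = t/(2 pi) for angle t in
    [pi/2, 2 pi] (max radius 1, three-quarters of a turn), rotated by
    2 pi s / 3.  Points are uniform in *arc length* along the curve; the
    radial noise SD is ``amplitude * radius``, so the transverse spread grows
    outward and the 2-D density is non-uniform.
    """
    if n < 10:
        raise ValueError("need at least 10 points per cluster")
    c = _noise_amplitude("spirals", noise_level, amplitude)
    rng = np.random.default_rng(seed)
    lo, hi = 0.5 * np.pi, 2.0 * np.pi
    grid = np.linspace(lo, hi, 1024)
    s_grid = _spiral_arclength(grid)   # arc length scales out in the inversion
    pts, labels = [], []
    for s in range(3):
        u = rng.uniform(s_grid[0], s_grid[-1], size=n)
        t = np.interp(u, s_grid, grid)
        radius = t / (2.0 * np.pi)
        radius = radius + rng.normal(0.0, 1.0, size=n) * c * radius
        angle = t + 2.0 * np.pi * s / 3.0
        pts.append(np.column_stack([radius * np.cos(angle), radius * np.sin(angle)]))
        labels.append(np.full(n, s))
    return LabeledDataset(np.vstack(pts), np.concatenate(labels), "spirals", seed,
                          {"noise_level": noise_level, "sd_per_radius": c,
                           "n_per_cluster": n})


def gen_three_rings(n: int = 100, noise_level: str = "low", seed: int = 0,
                    amplitude: Optional[float] = None,
                    gap: float = 0.2) -> LabeledDataset:
    """Central disc plus two concentric noisy rings, each ring split in halves.

    Five clusters: a uniform disc (radius 0.25) and the upper/lower halves of
    rings at radii 0.6 and 1.0 (constant radial Gaussian noise), with a small
    angular gap between the halves.  ``n`` points per cluster.
    """
    if n < 10:
        raise ValueError("need at least 10 points per cluster")
    sd = _noise_amplitude("rings", noise_level, amplitude)
    rng = np.random.default_rng(seed)
    pts = [np.column_stack(_disc(rng, n, 0.25))]
    labels = [np.zeros(n, dtype=int)]
    label = 1
    for radius in (0.6, 1.0):
        for lo, hi in ((gap / 2, np.pi - gap / 2),
                       (np.pi + gap / 2, 2 * np.pi - gap / 2)):
            theta = rng.uniform(lo, hi, size=n)
            r = radius + rng.normal(0.0, sd, size=n)
            pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
            labels.append(np.full(n, label))
            label += 1
    return LabeledDataset(np.vstack(pts), np.concatenate(labels), "rings", seed,
                          {"noise_level": noise_level, "sd": sd, "gap": gap,
                           "n_per_cluster": n})


def _disc(rng, n, radius):
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return r * np.cos(theta), r * np.sin(theta)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def _spiral_arclength(t: np.ndarray) -> np.ndarray:
    # arc length of the Archimedean spiral (t cos t, t sin t) from 0 to t
    return 0.5 * (t * np.sqrt(1.0 + t ** 2) + np.arcsinh(t))


def embed_swiss_roll(points2d: np.ndarray) -> np.ndarray:
    """Coil the plane isometrically into a 3-D swiss-roll.

    The x coordinate is mapped affinely onto *arc length* along the spiral
    (t cos t, t sin t) for t in the fixed winding interval [1.5 pi, 3.4 pi]
    (0.95 turn: the coil stays short of a full winding, so no part of the
    rolled sheet lies radially adjacent to another and the only structure
    the embedding adds is curvature), and y is scaled by the same global
    factor, so the embedding preserves the 2-D cluster geometry up to one
    overall scale: (x, y) -> (t(x) cos t(x), c * y, t(x) sin t(x)).  Row
    count and (scaled) y coordinate are preserved exactly.
    """
    P = np.asarray(points2d, dtype=float)
    if not np.isfinite(P).all():
        raise ValueError("non-finite coordinates")
    x, y = P[:, 0], P[:, 1]
    lo, hi = SWISS_ROLL_INTERVAL
    grid = np.linspace(lo, hi, 2048)
    s_grid = _spiral_arclength(grid)
    span = x.max() - x.min()
    scale = (s_grid[-1] - s_grid[0]) / (span if span > 0 else 1.0)
    s = s_grid[0] + scale * (x - x.min())
    t = np.interp(s, s_grid, grid)
    return np.column_stack([t * np.cos(t), scale * y, t * np.sin(t)])


def _data_range(P: np.ndarray) -> float:
    return float(np.max(P.max(axis=0) - P.min(axis=0)))


def add_embedding_noise(points: np.ndarray, sd: Optional[float] = None,
                        seed: int = 0) -> np.ndarray:
    """Add isotropic Gaussian noise; default sd is 1% of the data range."""
    P = np.asarray(points, dtype=float)
    if sd is None:
        sd = EMBED_NOISE_FRACTION * _data_range(P)
    rng = np.random.default_rng(seed)
    return P + rng.normal(0.0, sd, size=P.shape)


def _haar_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation: QR of a Gaussian matrix, sign-corrected, det +1."""
    Q, R = np.linalg.qr(rng.standard_normal((dim, dim)))
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def embed_10d(points3d: np.ndarray, sd: Optional[float] = None,
              seed: int = 0) -> np.ndarray:
    """Embed 3-D points in 10-D: zero-pad, Haar-random rotation, noise.

    With ``sd = 0`` the map is an isometry (rotation of the padded points);
    the default noise sd is 1% of the data range, applied in all 10
    dimensions.
    """
    P = np.asarray(points3d, dtype=float)
    if P.shape[1] != 3:
        raise ValueError("expected 3-D input points")
    rng = np.random.default_rng(seed)
    padded = np.hstack([P, np.zeros((P.shape[0], 7))])
    R = _haar_rotation(10, rng)
    out = padded @ R.T
    if sd is None:
        sd = EMBED_NOISE_FRACTION * _data_range(P)
    if sd > 0:
        out = out + rng.normal(0.0, sd, size=out.shape)
    return out


_MANIFOLDS = {"moons": gen_two_moons, "spirals": gen_three_spirals,
              "rings": gen_three_rings}
EMBEDDINGS = ("2d", "3d", "3dnoise", "10dnoise")


def make_manifold_dataset(shape: str, embedding: str = "2d",
                          noise_level: str = "low", n: int = 100,
                          seed: int = 0) -> LabeledDataset:
    """Generate a 2-D manifold problem and apply one of the four embeddings.

    Labels are untouched by the embedding; the sub-seeds of the embedding
    noise and rotation are derived deterministically from ``seed``.
    """
    if shape not in _MANIFOLDS:
        raise ValueError(f"shape must be one of {sorted(_MANIFOLDS)}, got {shape!r}")
    if embedding not in EMBEDDINGS:
        raise ValueError(f"embedding must be one of {EMBEDDINGS}, got {embedding!r}")
    base = _MANIFOLDS[shape](n=n, noise_level=noise_level, seed=seed)
    sub = [int(s.generate_state(1)[0] % 2**31)
           for s in np.random.SeedSequence([seed, 0xE3B]).spawn(2)]
    X = base.X
    if embedding != "2d":
        X = embed_swiss_roll(X)
    if embedding == "3dnoise":
        X = add_embedding_noise(X, seed=sub[0])
    elif embedding == "10dnoise":
        X = embed_10d(X, seed=sub[1])
    return LabeledDataset(X, base.labels, f"{shape}-{embedding}", seed,
                          {**base.params, "embedding": embedding})


_GENERATORS = {"a1": gen_a1, "a2": gen_a2, "a3": gen_a3, "a4": gen_a4, "a5": gen_a5}


def generate(name: str, seed: int = 0, **kwargs) -> LabeledDataset:
    """Generate any named benchmark: a1..a5 or moons/spirals/rings.

    Manifold problems accept ``embedding``, ``noise_level`` and ``n``.
    """
    if name in _GENERATORS:
        return _GENERATORS[name](seed)
    if name in _MANIFOLDS:
        return make_manifold_dataset(name, seed=seed, **kwargs)
    raise ValueError(f"unknown generator {name!r}")
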