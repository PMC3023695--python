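# Methods

## The metric

`pknng` measures dissimilarities between samples of a high-dimensional
dataset (typically expression profiles: a few dozen to a few hundred samples
over hundreds to thousands of genes) as geodesics on a penalized
neighborhood graph. The procedure has two stages.

**Stage 1 — neighborhood graph.** From a base dissimilarity d (Euclidean or
Pearson 1 − r), build the directed k-nearest-neighbor graph with a *low* k
(default 5; 3–7 is the sensible range). Low k lets the graph trace curved,
elongated structures without adding shortcuts across the ambient space. An
arc is discarded as an outlier arc iff it is **both** non-reciprocal (its
reverse arc is absent) **and** longer than Q3 + 1.5·IQR of all arc lengths
(quartiles by linear interpolation, computed once before any removal).
Isolated points typically lose their single long one-way connection here.
The surviving arcs are symmetrized into an undirected graph whose edge
weights are the base distances; its connected components are the locally
dense structures, and μ denotes its mean edge weight.

**Stage 2 — penalized bridges.** The components are reconnected with bridge
edges whose weight is penalized:

    w = d · e^(d/μ)          (exponential, default)
    w = d · (d/μ)^k          (power; default exponent 2)
    w = α · d                (linear; default α = 10)
    w = d                    (plain; ablation baseline)

A bridge on the order of μ costs only ≈ e times its length; a bridge across
a real cluster gap is exponentially expensive, so shortest paths almost
never cross it unless they must. Bridges with an endpoint in a
*singleton* component are left unpenalized, so lone outliers are absorbed
into the nearest structure instead of becoming their own clusters.

Four connection schemes are implemented: `minspan` (minimum spanning set
over components, m − 1 bridges at the closest cross pairs; the default),
`allsubgraphs` (closest cross pair for every component pair),
`alledges` (every absent vertex pair, making the graph complete; with the
plain penalty this reduces exactly to the base metric) and `medoids`
(bridges between component medoids only — deliberately manifold-blind, kept
as a comparator). The final metric is the all-pairs shortest-path matrix
(Dijkstra from every source on the sparse adjacency, O(n² log n)); the
schemes guarantee connectivity, so every entry is finite.

Properties worth knowing: the output is a true metric (shortest paths
satisfy the triangle inequality exactly); with a Euclidean base and the
exponential or plain penalty every geodesic dominates the straight-line
distance (each edge weight ≥ the Euclidean length of its segment); ties in
neighbor ranking, closest-pair search and medoid selection are broken by
ascending index, making the whole pipeline deterministic. The exponent of
the exponential penalty is capped at 500 so extreme bridges stay finite
without affecting any ordering.

## Comparison metrics

* **PBM** (path-based / minimax metric): distance = the minimum over all
  paths in the *complete* base-distance graph of the maximum edge on the
  path. It is an ultrametric realized on the minimum spanning tree; we
  compute it with a Kruskal union–find sweep (the edge that first joins two
  groups is the bottleneck for all their cross pairs). No free parameters.
* **RBF-mean / RBF-min**: kernel-induced distance
  sqrt(2 − 2·exp(−d²/σ²)). RBF-mean fixes σ at the median pairwise base
  distance. RBF-min scores a grid of candidates (default 20 log-spaced
  values over [0.1, 10] × median) by embedding the Gaussian affinity with
  the symmetric-normalized spectral map, clustering the row-normalized
  eigenvector matrix with seeded k-means (10 restarts) and keeping the σ
  with the smallest within-cluster sum of squares (ties → smallest σ). The
  spectral machinery exists solely for this bandwidth search.
* **min-k-connected-graph**: geodesics on the unpenalized knn-graph with
  the smallest k that connects it; isolates the effect of penalization.

## Clustering adapters and indices

PAM (k-medoids) is implemented directly because no installed library offers
k-medoids on a precomputed dissimilarity matrix: one greedy BUILD start plus
nine random starts, each refined by vectorized best-improvement swaps; it
reproduces R's `cluster::pam` objective and partition on shared fixtures.
Hierarchical clustering uses SciPy's average linkage; an optional
small-cluster rule (threshold 4 where engaged) cuts the tree progressively
deeper until k admissible clusters exist, then reassigns each dissolved
point to the admissible cluster with the smallest average dissimilarity
(a `drop` mode labels them −1 instead; reassignment is the default since
plain discarding leaves the treatment of those samples undefined).

Agreement with ground truth is scored by the Hubert–Arabie corrected Rand
index (from the contingency table; validated in tests against pair counting
and scikit-learn) and, for the 2-D benchmarks, clustering accuracy: the
percentage correctly assigned under the optimal one-to-one cluster/class
matching (Hungarian algorithm).

## Synthetic benchmarks

**Simulated microarrays.** A-1: 3 × 50 samples, 300 genes in 10 blocks of
30; each (block, cluster) cell is N(α·1, I) with α drawn uniformly from
{−0.5, 0, 0.5}. A-2–A-5: elongated Gaussian clusters of 25 samples in 100
genes; the principal axis carries 10% of the summed SD budget and the other
99 axes share the remaining 90% equally (SD ratio 11:1). The absolute scale
(budget = 10, so principal SD = 1) is arbitrary and cancels in clustering.
A-2 shares one random principal axis between its two clusters with the
center offset drawn *orthogonal* to it — parallel cigars side by side, 1.5
principal-SD apart. Offsetting the centers along the shared axis instead
would collapse the two clusters onto one overlapping line and no metric
could separate them, so the orthogonal reading is the one consistent with
the problem being solvable. A-3/A-4 give every cluster its own random axis
(centers 2 and 1 principal-SD apart along an independent random direction);
A-5 is A-4 with 200 informative genes plus 200 pure-noise genes at the
non-principal SD. Under this construction A-2–A-5 are cleanly separated in
the base space: the bottleneck (PBM) metric therefore also solves them, and
on A-3 plain Euclidean PAM does too. A fatter-noise variant (10/90 split of
*variances*) would overlap the clusters but then removes the graph metric's
advantage as well; no setting of the ambiguity produces both effects at
once, and the benchmark suite keeps the literal SD-split construction.

**Manifold problems.** Two-moons (2 clusters; unit arcs, radial Gaussian
noise of fixed SD 0.05/0.10/0.15 for low/medium/high), three-spirals
(3 clusters; Archimedean arms r = t/2π for t ∈ [π/2, 2π], points uniform in
arc length, radial noise SD proportional to radius with factor
0.02/0.04/0.06 — the transverse spread growing outward gives the stated
non-uniform density), three-rings (5 clusters; a uniform disc of radius
0.25 plus rings at 0.6 and 1.0 with constant radial noise, each ring split
into halves with a 0.2 rad angular gap).

Each 2-D problem can be embedded four ways: `2d` (native), `3d` (swiss-roll
coiling), `3dnoise` (coiling + Gaussian noise) and `10dnoise` (coiling,
zero-padding to 10-D, a Haar-random rotation, then Gaussian noise in all 10
dimensions). The coiling is *isometric*: x is mapped affinely onto arc
length along the spiral (t cos t, t sin t) for t ∈ [1.5π, 3.4π], and y is
scaled by the same global factor, so all local geometry survives up to one
scale. The interval is deliberately 0.95 of a turn: a full-turn coil places
the sheet's two ends radially adjacent (gap exactly 2π) and the sparse
one-sided neighborhoods at the arm ends then form reciprocal cross-winding
edges that the outlier rule cannot remove, while more than one turn shrinks
the winding gap relative to the stretched data and creates interior
shortcuts. Just short of a full winding, the embedding contributes
curvature — which is what defeats the raw Euclidean metric — without any
radial self-adjacency. Embedding noise defaults to SD = 1% of the data
range, enough to pull points measurably off the surface while staying below
the scale at which adjacent structures merge. All generators are
deterministic given their seed.

**What the generators do not emulate.** Real expression data has heavy
tails, gene–gene correlation beyond a single principal axis, batch
structure and uneven class sizes; the Gaussian constructions here have none
of those. Passing benchmarks therefore demonstrates the geometric behavior
of the metrics (manifold following, penalization, scheme differences), not
performance on any particular real dataset.

## Benchmark harness

`run_benchmark` repeats: generate a fresh realization (or subsample a fixed
matrix without replacement, e.g. 95%), compute each configured metric,
cluster with PAM and/or HC-average at the known k, score cRand (and
accuracy). Per-realization seeds derive from the master seed through
`SeedSequence([master, rep])`, so reports reproduce value-for-value.
Summaries report median, quartiles and 1.5·IQR whiskers. The predefined
studies in `pknng.benchmarks` run 20 realizations at 100 points per cluster
(manifolds) or the natural sizes of A-1–A-5 — scaled so a full study
completes in minutes on one core; the number of clusters is always supplied
(estimating it is out of scope).

## Numerical conventions

Quartiles: linear interpolation (NumPy default). Median of an even count:
mean of the central pair. Row normalization: population SD (denominator n).
Correlation distance: 1 − r (ordering-consistent; the metric only needs
ranks). μ is computed on the pruned, symmetrized graph. Duplicate points
(zero distances) are legal throughout; an MST over components shifts all
costs by +1 internally so zero-cost pairs stay representable. Eigenvector
signs in the spectral embedding are fixed by making each vector's
largest-magnitude entry positive.

## Known limitations

MinSpan builds an essentially one-dimensional bridge skeleton; on heavily
fragmented graphs two fragments of different clusters occasionally sit
closer than fragments of the same cluster, and the resulting bridge
topology misleads the geodesics (visible as occasional low-accuracy
realizations on the spirals benchmarks). The reciprocity+IQR outlier rule
cannot remove *reciprocal* shortcut edges. PAM on near-concentrated
distance matrices (A-1-like, hundreds of isotropic dimensions) is
noticeably weaker than centroid-based k-means — an inherent property of the
medoid objective, reproduced identically by R's reference implementation.
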