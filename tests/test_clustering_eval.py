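import itertools

import numpy as np
import pytest
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from pknng import (BenchmarkConfig, boxplot_summary, cluster_hc_average,
                   cluster_pam, clustering_accuracy, corrected_rand,
                   euclidean_distances, run_benchmark)


def two_triples():
    X = np.array([[0, 0], [0.2, 0], [0, 0.2], [30, 30], [30.2, 30], [30, 30.2]],
                 dtype=float)
    return euclidean_distances(X), np.repeat([0, 1], 3)


class TestPam:
    def test_far_apart_triples_recovered(self):
        D, truth = two_triples()
        res = cluster_pam(D, 2, seed=0)
        assert corrected_rand(res.labels, truth) == 1.0

    def test_k_equals_n_zero_cost(self):
        D, _ = two_triples()
        res = cluster_pam(D, 6, seed=0)
        assert res.meta["cost"] == 0.0
        assert len(set(res.labels.tolist())) == 6

    def test_matches_exhaustive_medoid_search(self, rng):
        from pknng import PairwiseDistances
        for _ in range(10):
            d = euclidean_distances(rng.normal(size=(8, 2))).values
            res = cluster_pam(PairwiseDistances(d), 2, seed=1)
            best = min(d[:, list(pair)].min(axis=1).sum()
                       for pair in itertools.combinations(range(8), 2))
            assert res.meta["cost"] == pytest.approx(best)

    def test_objective_never_increases(self, rng):
        D = euclidean_distances(rng.normal(size=(30, 3)))
        res = cluster_pam(D, 4, seed=2)
        trace = res.meta["cost_trace"]
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_deterministic_given_seed(self, rng):
        D = euclidean_distances(rng.normal(size=(25, 3)))
        a = cluster_pam(D, 3, seed=5)
        b = cluster_pam(D, 3, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_rejects_bad_k(self):
        D, _ = two_triples()
        with pytest.raises(ValueError):
            cluster_pam(D, 1)
        with pytest.raises(ValueError):
            cluster_pam(D, 7)


def naive_average_linkage(d, k):
    """O(n^3) agglomerative average linkage by direct cluster-pair means."""
    clusters = [[i] for i in range(d.shape[0])]
    while len(clusters) > k:
        best = (np.inf, None)
        for a, b in itertools.combinations(range(len(clusters)), 2):
            link = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if link < best[0] - 1e-15:
                best = (link, (a, b))
        a, b = best[1]
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(d.shape[0], dtype=int)
    for c, members in enumerate(clusters):
        labels[members] = c
    return labels


class TestHcAverage:
    def test_two_tight_pairs(self):
        D = euclidean_distances(np.array([[0, 0], [0.1, 0], [5, 5], [5.1, 5]],
                                         dtype=float))
        res = cluster_hc_average(D, 2)
        assert corrected_rand(res.labels, [0, 0, 1, 1]) == 1.0

    def test_matches_naive_linkage_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 8))
            D = euclidean_distances(rng.normal(size=(n, 3)))
            for k in range(2, n):
                got = cluster_hc_average(D, k).labels
                expect = naive_average_linkage(D.values, k)
                assert adjusted_rand_score(got, expect) == 1.0

    def test_small_cluster_rule_reassigns(self):
        # 2 big groups plus a lone point: with threshold 3 the singleton is
        # dissolved into its nearest big cluster
        X = np.vstack([np.zeros((4, 2)) + [[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1]],
                       np.zeros((4, 2)) + [[8, 8], [8.1, 8], [8, 8.1], [8.1, 8.1]],
                       [[30.0, 30.0]]])
        D = euclidean_distances(X)
        res = cluster_hc_average(D, 2, min_cluster_size=3)
        assert res.meta["n_dissolved_points"] >= 1
        assert set(res.labels.tolist()) == {0, 1}
        assert res.labels[8] == res.labels[4]  # outlier joins nearest group

    def test_drop_mode_marks_points(self):
        X = np.vstack([np.random.default_rng(0).normal(size=(4, 2)),
                       np.random.default_rng(1).normal(loc=8, size=(4, 2)),
                       [[30.0, 30.0]]])
        D = euclidean_distances(X)
        res = cluster_hc_average(D, 2, min_cluster_size=3, dissolved="drop")
        if res.meta["n_dissolved_points"]:
            assert (res.labels == -1).sum() == res.meta["n_dissolved_points"]

    def test_threshold_one_is_plain_cut(self, rng):
        D = euclidean_distances(rng.normal(size=(10, 2)))
        a = cluster_hc_average(D, 3, min_cluster_size=1).labels
        from scipy.cluster.hierarchy import fcluster, linkage
        z = linkage(squareform(D.values, checks=False), method="average")
        b = fcluster(z, t=3, criterion="maxclust") - 1
        assert adjusted_rand_score(a, b) == 1.0


def pair_counting_ari(a, b):
    """Direct pair-counting oracle for the adjusted Rand index."""
    n = len(a)
    same_a = np.equal.outer(a, a)
    same_b = np.equal.outer(b, b)
    iu = np.triu_indices(n, 1)
    n11 = np.sum(same_a[iu] & same_b[iu])
    n00 = np.sum(~same_a[iu] & ~same_b[iu])
    n10 = np.sum(same_a[iu] & ~same_b[iu])
    n01 = np.sum(~same_a[iu] & same_b[iu])
    total = n * (n - 1) / 2
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


class TestCorrectedRand:
    def test_identical_partitions(self):
        assert corrected_rand([0, 0, 1, 1, 2], [5, 5, 3, 3, 9]) == 1.0

    def test_known_negative_value(self):
        assert corrected_rand([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_relabeling_invariance(self, rng):
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 4, size=40)
        perm = {0: 7, 1: 2, 2: 0, 3: 11}
        b2 = np.array([perm[x] for x in b])
        assert corrected_rand(a, b) == pytest.approx(corrected_rand(a, b2))

    def test_matches_pair_counting_and_sklearn(self, rng):
        for _ in range(50):
            a = rng.integers(0, 4, size=30)
            b = rng.integers(0, 3, size=30)
            got = corrected_rand(a, b)
            assert got == pytest.approx(pair_counting_ari(a, b))
            assert got == pytest.approx(adjusted_rand_score(a, b))

    def test_near_zero_under_independent_shuffles(self, rng):
        truth = np.repeat([0, 1, 2], 20)
        vals = [corrected_rand(rng.permutation(truth), truth)
                for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.05
        assert max(vals) <= 1.0

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            corrected_rand([0, 1], [0, 1, 2])


class TestClusteringAccuracy:
    def test_relabeled_perfect_partition(self):
        assert clustering_accuracy([2, 2, 0, 0], [7, 7, 9, 9]) == 100.0

    def test_single_cluster_on_balanced_truth(self):
        assert clustering_accuracy([0, 0, 0, 0], [0, 0, 1, 1]) == 50.0

    def test_matches_exhaustive_matching_oracle(self, rng):
        for _ in range(30):
            pred = rng.integers(0, 3, size=12)
            truth = rng.integers(0, 3, size=12)
            got = clustering_accuracy(pred, truth)
            best = 0
            for perm in itertools.permutations(range(3)):
                correct = sum(perm[p] == t for p, t in zip(pred, truth))
                best = max(best, correct)
            assert got == pytest.approx(100.0 * best / 12)

    def test_at_least_chance_on_balanced_truth(self, rng):
        truth = np.repeat(np.arange(4), 10)
        pred = rng.integers(0, 4, size=40)
        assert clustering_accuracy(pred, truth) >= 100.0 / 4


class TestBoxplotSummary:
    def test_matches_independent_quantiles(self, rng):
        v = rng.normal(size=37)
        s = boxplot_summary(v)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        assert s["median"] == pytest.approx(med)
        assert s["q1"] == pytest.approx(q1) and s["q3"] == pytest.approx(q3)
        iqr = q3 - q1
        inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        assert s["whisker_low"] == pytest.approx(inside.min())
        assert s["whisker_high"] == pytest.approx(inside.max())


class TestRunBenchmark:
    def cfg(self, **kw):
        base = dict(metrics=[{"name": "pknng"}, {"name": "euclidean"}],
                    methods=["pam"], n_clusters=2, generator="moons",
                    generator_params={"n": 30, "noise_level": "low"},
                    reps=2, seed=42, compute_accuracy=True)
        base.update(kw)
        return BenchmarkConfig(**base)

    def test_single_rep_separable_data_perfect(self):
        report = run_benchmark(self.cfg(reps=1))
        key = [k for k in report.crand if k.startswith("pknng")][0]
        assert report.crand[key] == [1.0]

    def test_same_seed_identical_reports(self):
        a = run_benchmark(self.cfg())
        b = run_benchmark(self.cfg())
        assert a.crand == b.crand and a.accuracy == b.accuracy

    def test_subsampling_row_count(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(40, 3))
        labels = rng.integers(0, 2, size=40)
        cfg = BenchmarkConfig(metrics=[{"name": "euclidean"}], methods=["pam"],
                              n_clusters=2, data=data, labels=labels,
                              generator=None, reps=1, subsample_fraction=0.95,
                              seed=1)
        report = run_benchmark(cfg)
        assert report.crand  # ran on floor(0.95 * 40) = 38 rows without error

    def test_failures_recorded_not_fatal(self):
        cfg = self.cfg(metrics=[{"name": "rbf-min"}, {"name": "euclidean"}],
                       n_clusters=25, reps=1,
                       generator_params={"n": 12, "noise_level": "low"})
        report = run_benchmark(cfg)
        assert report.failures or report.crand

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BenchmarkConfig(metrics=[], methods=["pam"], n_clusters=2)
        with pytest.raises(ValueError):
            self.cfg(subsample_fraction=0.0)
        with pytest.raises(ValueError):
            self.cfg(methods=["kmeans"])
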