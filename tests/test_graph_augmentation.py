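import itertools

import numpy as np
import pytest

from pknng import (PenaltySpec, build_knn_arcs, connect, connect_all_edges,
                   connect_all_subgraphs, connect_medoids, connect_minspan,
                   euclidean_distances, penalty_weight, prune_outlier_arcs,
                   symmetrize)
from conftest import flood_fill_components


def clustered_line(*groups):
    """1-D points in well-separated groups -> (graph, distances)."""
    xs = [x for g in groups for x in g]
    D = euclidean_distances(np.array(xs, dtype=float).reshape(-1, 1))
    g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=min(2, len(xs) - 1))))
    return g, D


class TestPenaltyWeight:
    def test_exponential_values(self):
        assert penalty_weight(1.0, 1.0) == pytest.approx(np.e)
        assert penalty_weight(0.0, 1.0) == 0.0

    def test_other_families(self):
        assert penalty_weight(2.0, 1.0, PenaltySpec("power", k_exp=2)) == 8.0
        assert penalty_weight(2.0, 1.0, PenaltySpec("linear", alpha=3.0)) == 6.0
        assert penalty_weight(2.0, 1.0, PenaltySpec("plain")) == 2.0

    def test_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            penalty_weight(1.0, 0.0)

    def test_exponential_ratio_strictly_increasing(self):
        d = np.linspace(0.1, 5.0, 40)
        ratio = penalty_weight(d, 1.0) / d
        assert (np.diff(ratio) > 0).all()

    def test_long_bridges_cost_more_than_e_times_length(self):
        d = np.array([1.5, 2.0, 4.0])
        assert (penalty_weight(d, 1.0) > np.e * d).all()


class TestMinSpan:
    def test_single_component_no_bridges(self):
        g, D = clustered_line([0.0, 1.0, 2.0])
        aug = connect_minspan(g, D)
        assert aug.bridges == [] and aug.is_connected()

    def test_two_components_known_weight(self):
        # k=1 chains give four unit edges, so mu = 1; closest cross pair is
        # (2, 3) at distance 5 -> bridge weight 5 e^5
        D = euclidean_distances(
            np.array([0.0, 1.0, 2.0, 7.0, 8.0, 9.0]).reshape(-1, 1))
        g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=1)))
        assert g.n_components == 2 and g.mu == pytest.approx(1.0)
        aug = connect_minspan(g, D)
        (b,) = aug.bridges
        assert (b.i, b.j, b.base) == (2, 3, 5.0)
        assert b.weight == pytest.approx(5.0 * np.e ** 5)

    def test_bridge_count_and_connectivity(self, rng):
        for _ in range(10):
            X = np.vstack([rng.normal(loc=(30 * c, 0), scale=0.5, size=(4, 2))
                           for c in range(4)])
            D = euclidean_distances(X)
            g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=2)))
            aug = connect_minspan(g, D)
            assert len(aug.bridges) == g.n_components - 1
            i, j, _ = aug.all_edges()
            _, n_comp = flood_fill_components(g.n, list(zip(i, j)))
            assert n_comp == 1

    def test_matches_exhaustive_spanning_tree_oracle(self, rng):
        for trial in range(5):
            X = np.vstack([rng.normal(loc=(15 * c, 10 * (c % 2)), scale=0.4,
                                      size=(3, 2)) for c in range(4)])
            D = euclidean_distances(X)
            g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=1)))
            m = g.n_components
            if m < 3:
                continue
            aug = connect_minspan(g, D, PenaltySpec("plain"))
            total = sum(b.base for b in aug.bridges)
            # oracle: cheapest spanning tree over components by brute force
            comp = g.components
            cost = {}
            for a, b in itertools.combinations(range(m), 2):
                cost[(a, b)] = D.values[np.ix_(np.flatnonzero(comp == a),
                                               np.flatnonzero(comp == b))].min()
            best = np.inf
            for tree in itertools.combinations(cost, m - 1):
                _, n_comp = flood_fill_components(m, [(a, b, 0) for a, b in tree])
                if n_comp == 1:
                    best = min(best, sum(cost[e] for e in tree))
            assert total == pytest.approx(best)


class TestAllSubGraphs:
    def test_two_components_identical_to_minspan(self):
        g, D = clustered_line([0.0, 1.0], [7.0, 8.0])
        a = connect_minspan(g, D)
        b = connect_all_subgraphs(g, D)
        assert [(x.i, x.j, x.weight) for x in a.bridges] == \
               [(x.i, x.j, x.weight) for x in b.bridges]

    def test_bridge_count_and_superset_of_minspan(self, rng):
        X = np.vstack([rng.normal(loc=(20 * c, 0), scale=0.4, size=(3, 2))
                       for c in range(3)])
        D = euclidean_distances(X)
        g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=1)))
        assert g.n_components == 3
        allsub = connect_all_subgraphs(g, D)
        minspan = connect_minspan(g, D)
        assert len(allsub.bridges) == 3
        assert {(b.i, b.j) for b in minspan.bridges} <= \
               {(b.i, b.j) for b in allsub.bridges}

    def test_each_bridge_is_closest_cross_pair(self, rng):
        X = np.vstack([rng.normal(loc=(20 * c, 5 * c), scale=0.4, size=(3, 2))
                       for c in range(3)])
        D = euclidean_distances(X)
        g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=1)))
        aug = connect_all_subgraphs(g, D)
        comp = g.components
        for b in aug.bridges:
            a_idx = np.flatnonzero(comp == comp[b.i])
            b_idx = np.flatnonzero(comp == comp[b.j])
            assert b.base == pytest.approx(
                D.values[np.ix_(a_idx, b_idx)].min())


class TestAllEdges:
    def test_complete_input_no_bridges(self):
        D = euclidean_distances(np.arange(4.0).reshape(-1, 1))
        g = symmetrize(build_knn_arcs(D, k=3))
        assert connect_all_edges(g, D).bridges == []

    def test_bridge_count_complement(self):
        g, D = clustered_line([0.0, 1.0], [7.0, 8.0])
        aug = connect_all_edges(g, D)
        assert len(aug.bridges) == 6 - g.n_edges
        # result is complete
        assert g.n_edges + len(aug.bridges) == 6


class TestMedoids:
    def test_middle_point_is_medoid(self):
        g, D = clustered_line([0.0, 1.0, 2.0], [50.0, 51.0, 52.0])
        aug = connect_medoids(g, D)
        (b,) = aug.bridges
        assert (b.i, b.j) == (1, 4)  # midpoints of each triple

    def test_single_component_no_bridges(self):
        g, D = clustered_line([0.0, 1.0, 2.0])
        assert connect_medoids(g, D).bridges == []

    def test_medoid_matches_row_sum_argmin(self, rng):
        X = np.vstack([rng.normal(loc=(25 * c, 0), scale=1.0, size=(5, 2))
                       for c in range(2)])
        D = euclidean_distances(X)
        g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=2)))
        aug = connect_medoids(g, D)
        comp = g.components
        for b in aug.bridges:
            for end in (b.i, b.j):
                idx = np.flatnonzero(comp == comp[end])
                sums = D.values[np.ix_(idx, idx)].sum(axis=1)
                assert end == idx[np.argmin(sums)]


class TestSingletonRule:
    def test_bridge_to_isolated_point_unpenalized(self):
        # far point gets isolated by pruning; its bridge keeps base weight
        g, D = clustered_line([0.0, 1.0, 2.2], [100.0])
        assert g.component_sizes().min() == 1
        aug = connect_minspan(g, D)
        (b,) = aug.bridges
        assert b.provenance == "singleton_bridge"
        assert b.weight == pytest.approx(b.base)

    def test_regular_bridges_keep_penalty(self):
        D = euclidean_distances(np.array([0.0, 1.0, 7.0, 8.0]).reshape(-1, 1))
        g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=1)))
        (b,) = connect_minspan(g, D).bridges
        assert b.provenance == "bridge" and b.weight > b.base


class TestSchemesShared:
    @pytest.mark.parametrize("scheme", ["minspan", "allsubgraphs", "alledges",
                                        "medoids"])
    def test_every_scheme_connects(self, rng, scheme):
        X = np.vstack([rng.normal(loc=(20 * c, 0), scale=0.5, size=(4, 2))
                       for c in range(3)])
        D = euclidean_distances(X)
        g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=2)))
        aug = connect(g, D, scheme=scheme)
        i, j, _ = aug.all_edges()
        _, n_comp = flood_fill_components(g.n, list(zip(i, j)))
        assert n_comp == 1

    @pytest.mark.parametrize("scheme", ["minspan", "allsubgraphs", "alledges",
                                        "medoids"])
    def test_plain_family_bridges_carry_base_distance(self, rng, scheme):
        X = np.vstack([rng.normal(loc=(20 * c, 0), scale=0.5, size=(4, 2))
                       for c in range(3)])
        D = euclidean_distances(X)
        g = symmetrize(prune_outlier_arcs(build_knn_arcs(D, k=2)))
        aug = connect(g, D, scheme=scheme, spec=PenaltySpec("plain"))
        for b in aug.bridges:
            assert b.weight == pytest.approx(b.base)

    def test_unknown_scheme_rejected(self, rng):
        g, D = clustered_line([0.0, 1.0], [7.0, 8.0])
        with pytest.raises(ValueError):
            connect(g, D, scheme="nope")
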