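"""Weighted k-means against exhaustive enumeration, silhouette against the
direct per-point formula, anchor-weight semantics, grid bookkeeping."""

from itertools import product

import numpy as np
import pytest

from itembank.cluster import (
    AnchoredKMeans,
    WeightedPointSet,
    build_weighted_points,
    silhouette,
    silhouette_samples,
    weighted_kmeans,
)
from itembank.embedding import EmbeddingMatrix, WordFilterSpec
from itembank.selection import ClusteringGridSearch, ParamGrid


def matrix(X, prefix="p"):
    X = np.asarray(X, dtype=float)
    return EmbeddingMatrix([f"{prefix}{i}" for i in range(len(X))], X)


# ---------------------------------------------------------------- oracles


def brute_force_weighted_inertia(X, w, k):
    """Exhaustive minimum weighted within-cluster sum of squares."""
    n = len(X)
    best = np.inf
    for assign in product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        total = 0.0
        for c in range(k):
            mask = np.array(assign) == c
            centroid = np.average(X[mask], axis=0, weights=w[mask])
            total += float(np.sum(w[mask] * np.sum((X[mask] - centroid) ** 2, axis=1)))
        best = min(best, total)
    return best


def silhouette_formula(X, labels):
    """Direct a/b per-point silhouette, no vectorized shortcuts."""
    n = len(X)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


# ---------------------------------------------------------------- weights


class TestWeightedPoints:
    def test_total_anchor_mass_is_weight_times_items(self):
        items = matrix(np.zeros((100, 3)))
        anchors = matrix(np.ones((10, 3)), "a")
        ps = build_weighted_points(items, anchors, 0.5)
        anchor_w = ps.weights[ps.is_anchor]
        assert np.allclose(anchor_w, 5.0)
        assert np.isclose(anchor_w.sum(), 50.0)
        assert np.allclose(ps.weights[~ps.is_anchor], 1.0)

    def test_weight_quarter_splits_evenly(self):
        ps = build_weighted_points(
            matrix(np.zeros((80, 2))), matrix(np.ones((20, 2)), "a"), 0.25
        )
        assert np.allclose(ps.weights[ps.is_anchor], 1.0)

    def test_zero_weight_excludes_anchors(self):
        ps = build_weighted_points(
            matrix(np.zeros((5, 2))), matrix(np.ones((2, 2)), "a"), 0.0
        )
        assert len(ps.X) == 5
        assert not ps.is_anchor.any()

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_weighted_points(
                matrix(np.zeros((4, 3))), matrix(np.ones((2, 2)), "a"), 0.1
            )

    def test_positive_weight_without_anchors_rejected(self):
        with pytest.raises(ValueError):
            build_weighted_points(matrix(np.zeros((4, 3))), None, 0.1)


# ---------------------------------------------------------------- k-means


class TestWeightedKMeans:
    def test_separable_pairs_grouped(self):
        X = np.array([[0.0, 0], [0.1, 0], [10, 10], [10.1, 10]])
        res = AnchoredKMeans(matrix(X), k=2, seed=0).fit()
        lab = res.labels()
        assert lab[0] == lab[1] and lab[2] == lab[3] and lab[0] != lab[2]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_optimum_on_tiny_instances(self, seed, k):
        rng = np.random.default_rng(seed)
        n = 7
        X = rng.normal(size=(n, 2))
        w = rng.uniform(0.2, 3.0, size=n)
        ps = WeightedPointSet(
            X=X, weights=w, is_anchor=np.zeros(n, dtype=bool),
            ids=[f"p{i}" for i in range(n)],
        )
        _, _, inertia = weighted_kmeans(ps, k=k, seed=seed, n_init=20)
        oracle = brute_force_weighted_inertia(X, w, k)
        assert inertia == pytest.approx(oracle, rel=1e-6)

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        items = matrix(X)
        a = AnchoredKMeans(items, k=3, seed=5).fit()
        ps = WeightedPointSet(
            X=X, weights=np.full(30, 1.0), is_anchor=np.zeros(30, dtype=bool),
            ids=items.ids,
        )
        labels, _, inertia = weighted_kmeans(ps, k=3, seed=5)
        assert np.array_equal(a.labels(items.ids), labels)
        assert a.inertia == pytest.approx(inertia)

    def test_vanishing_anchor_weight_converges_to_item_only(self):
        rng = np.random.default_rng(4)
        items = matrix(rng.normal(size=(40, 3)))
        anchors = matrix(rng.normal(size=(4, 3)), "a")
        plain = AnchoredKMeans(items, k=4, anchor_weight=0.0, seed=9).fit()
        tiny = AnchoredKMeans(items, anchors, k=4, anchor_weight=1e-9, seed=9).fit()
        assert plain.assignments == tiny.assignments

    def test_k_larger_than_points_rejected(self):
        with pytest.raises(ValueError):
            AnchoredKMeans(matrix(np.zeros((3, 2))), k=4).fit()

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        items = matrix(rng.normal(size=(50, 5)))
        a = AnchoredKMeans(items, k=5, seed=21).fit()
        b = AnchoredKMeans(items, k=5, seed=21).fit()
        assert a.assignments == b.assignments
        assert np.array_equal(a.centroids, b.centroids)


# ------------------------------------------------------------- silhouette


class TestSilhouette:
    def test_coincident_far_clusters_score_one(self):
        X = np.array([[0.0, 0]] * 3 + [[50.0, 50]] * 3)
        m = matrix(X)
        labels = {m.ids[i]: int(i >= 3) for i in range(6)}
        assert silhouette(m, labels) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 3))
        labels_arr = rng.integers(0, 2, size=12)
        if len(set(labels_arr)) < 2:
            labels_arr[0] = 1 - labels_arr[0]
        m = matrix(X)
        labels = {m.ids[i]: int(labels_arr[i]) for i in range(12)}
        assert silhouette(m, labels) == pytest.approx(
            silhouette_formula(X, labels_arr), abs=1e-9
        )

    def test_single_cluster_errors(self):
        m = matrix(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            silhouette(m, {i: 0 for i in m.ids})

    def test_bounded_and_merging_planted_clusters_hurts(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        X = np.vstack([c + rng.normal(scale=0.3, size=(15, 2)) for c in centers])
        m = matrix(X)
        true = {m.ids[i]: i // 15 for i in range(45)}
        merged = {m.ids[i]: min(i // 15, 1) for i in range(45)}
        s_true, s_merged = silhouette(m, true), silhouette(m, merged)
        assert -1.0 <= s_merged < s_true <= 1.0

    def test_samples_indexed_by_item(self):
        X = np.array([[0.0, 0], [0.1, 0], [9, 9], [9.1, 9]])
        m = matrix(X)
        s = silhouette_samples(m, {m.ids[i]: int(i >= 2) for i in range(4)})
        assert list(s.index) == m.ids
        assert (s > 0.9).all()


# ------------------------------------------------------------ grid search


class TestGridSearch:
    def test_full_grid_enumerates_all_combinations(self):
        grid = ParamGrid()  # k 4..40, 4 filters, 4 dims, 4 weights
        assert len(grid) == 37 * 4 * 4 * 4 == 2368
        assert len(grid.combinations()) == 2368

    def test_retains_requested_count_ranked_by_heuristic(self, small_world, backend):
        cleaned, truth, anchors = small_world
        grid = ParamGrid(
            k_values=(3, 4, 5),
            filters=(WordFilterSpec("none"),),
            dims=(10,),
            anchor_weights=(0.0, 0.25),
        )
        results = ClusteringGridSearch(
            cleaned, anchors, grid, backend=backend, seed=2, n_init=4
        ).fit(retain=4)
        assert len(results.all_clusterings) == 6
        assert len(results.retained) == 4
        scores = [r.heuristic_score for r in results.retained]
        assert scores == sorted(scores, reverse=True)
        assert results.best.heuristic_score == max(
            r.heuristic_score for r in results.all_clusterings
        )

    def test_retain_larger_than_grid_warns_and_returns_all(self, small_world, backend):
        cleaned, truth, anchors = small_world
        grid = ParamGrid(
            k_values=(3, 4),
            filters=(WordFilterSpec("none"),),
            dims=(5,),
            anchor_weights=(0.0,),
        )
        with pytest.warns(UserWarning, match="retain"):
            results = ClusteringGridSearch(
                cleaned, anchors, grid, backend=backend, seed=2, n_init=4
            ).fit(retain=10)
        assert len(results.retained) == 2

    def test_fixed_seed_gives_identical_ranking(self, small_world, backend):
        cleaned, truth, anchors = small_world
        grid = ParamGrid(
            k_values=(3, 4, 5),
            filters=(WordFilterSpec("none"),),
            dims=(5,),
            anchor_weights=(0.25,),
        )
        run = lambda: ClusteringGridSearch(
            cleaned, anchors, grid, backend=backend, seed=7, n_init=4
        ).fit(retain=3)
        a, b = run(), run()
        assert [r.params for r in a.retained] == [r.params for r in b.retained]
        assert a.best.assignments == b.best.assignments

    def test_table_mirrors_reporting_columns(self, small_world, backend):
        cleaned, truth, anchors = small_world
        grid = ParamGrid(
            k_values=(4,), filters=(WordFilterSpec("none"),), dims=(5,),
            anchor_weights=(0.25,),
        )
        results = ClusteringGridSearch(
            cleaned, anchors, grid, backend=backend, seed=1, n_init=4
        ).fit(retain=1)
        table = results.table()
        for col in ("K", "Word filtering", "PCA dimension", "Anchor weight", "Silhouette score"):
            assert col in table.columns

    def test_positive_weights_require_anchor_terms(self, small_world, backend):
        cleaned, _, _ = small_world
        grid = ParamGrid(
            k_values=(4,), filters=(WordFilterSpec("none"),), dims=(5,),
            anchor_weights=(0.25,),
        )
        with pytest.raises(ValueError, match="anchor"):
            ClusteringGridSearch(cleaned, [], grid, backend=backend)
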