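import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans

from wirespec.region_clustering import (
    ImportanceProfile,
    NUCLEIC_ACID_RICH,
    PROTEIN_RICH,
    classify_regions,
    extract_band_features,
    kmeans_pp,
    rf_importance,
    select_k_by_silhouette,
    silhouette,
    smooth_importance,
    top_bands,
)
from wirespec.spectra_core import SpectrumSet, WavenumberGrid


def brute_force_silhouette(X, labels):
    """Independent O(n^2) loop implementation of the silhouette mean."""
    n = len(X)
    s = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            s.append(0.0)
            continue
        a_i = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b_i = min(
            np.mean(
                [np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == lab]
            )
            for lab in set(labels)
            if lab != labels[i]
        )
        s.append((b_i - a_i) / max(a_i, b_i))
    return float(np.mean(s))


def two_blobs(rng, n=40, sep=20.0, dim=2, spread=0.5):
    a = rng.normal(0.0, spread, size=(n, dim))
    b = rng.normal(sep, spread, size=(n, dim))
    return np.vstack([a, b])


class TestKmeansPP:
    def test_two_blobs_partition(self):
        rng = np.random.default_rng(0)
        X = two_blobs(rng)
        res = kmeans_pp(X, 2, seed=0)
        first, second = res.labels[:40], res.labels[40:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_n_equals_k_zero_inertia(self):
        X = np.array([[0.0, 0], [5, 5], [10, 0], [0, 10]])
        res = kmeans_pp(X, 4, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.labels)) == 4

    def test_beats_random_label_baseline(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 10, size=(60, 3))
        res = kmeans_pp(X, 3, seed=0)
        # brute-force baseline: random assignments, centers = label means
        worst = np.inf
        for trial in range(20):
            labels = rng.integers(0, 3, 60)
            if len(set(labels)) < 3:
                continue
            inertia = sum(
                np.sum((X[labels == lab] - X[labels == lab].mean(axis=0)) ** 2)
                for lab in range(3)
            )
            worst = min(worst, inertia)
        assert res.inertia <= worst

    def test_invalid_k(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            kmeans_pp(X, 1, seed=0)
        with pytest.raises(ValueError):
            kmeans_pp(np.random.default_rng(0).normal(size=(3, 2)), 4, seed=0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        r1 = kmeans_pp(X, 3, seed=5)
        r2 = kmeans_pp(X, 3, seed=5)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_inertia_non_increasing_over_lloyd_iterations(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 5))
        inertias = []
        for max_iter in (1, 2, 3, 5, 10, 50):
            km = KMeans(
                n_clusters=3, init="k-means++", n_init=1, max_iter=max_iter,
                tol=0.0, random_state=7,
            ).fit(X)
            inertias.append(km.inertia_)
        assert np.all(np.diff(inertias) <= 1e-9)

    def test_normalized_intensity_range(self):
        rng = np.random.default_rng(4)
        res = kmeans_pp(two_blobs(rng), 2, seed=0)
        assert np.all(res.normalized_intensity >= 0)
        assert np.all(res.normalized_intensity <= 1)


class TestSilhouette:
    def test_hand_computed_two_pairs(self):
        # {0,1} vs {5,6} in 1-D
        X = np.array([[0.0], [1.0], [5.0], [6.0]])
        labels = np.array([0, 0, 1, 1])
        sc, a, b = silhouette(X, labels)
        # sample 0: a=1, b=(5+6)/2=5.5 -> 0.81818...
        expected = np.mean(
            [(5.5 - 1) / 5.5, (4.5 - 1) / 4.5, (4.5 - 1) / 4.5, (5.5 - 1) / 5.5]
        )
        assert sc == pytest.approx(expected, abs=1e-12)
        assert sc == pytest.approx(0.7980, abs=1e-4)

    def test_coincident_clusters_far_apart(self):
        X = np.array([[0.0, 0], [0, 0], [9, 9], [9, 9]])
        sc, a, b = silhouette(X, np.array([0, 0, 1, 1]))
        assert sc == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((600, 3))
        labels = rng.integers(0, 2, 600)
        sc, _, _ = silhouette(X, labels)
        assert abs(sc) < 0.05

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((5, 2)), np.zeros(5, dtype=int))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for n, k in [(10, 2), (25, 3), (50, 4)]:
            X = rng.uniform(-5, 5, size=(n, 3))
            labels = rng.integers(0, k, n)
            while len(set(labels)) < 2:
                labels = rng.integers(0, k, n)
            sc, _, _ = silhouette(X, labels)
            assert sc == pytest.approx(
                brute_force_silhouette(X, labels), abs=1e-12
            )

    def test_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            X = rng.normal(size=(30, 2))
            labels = rng.integers(0, 3, 30)
            if len(set(labels)) < 2:
                continue
            sc, _, _ = silhouette(X, labels)
            assert -1.0 <= sc <= 1.0


class TestSelectK:
    def test_two_blobs_selects_two(self):
        rng = np.random.default_rng(8)
        assert select_k_by_silhouette(two_blobs(rng), 2, 5, seed=0) == 2

    def test_three_blobs_selects_three(self):
        rng = np.random.default_rng(9)
        X = np.vstack(
            [
                rng.normal((0, 0), 0.4, size=(30, 2)),
                rng.normal((15, 0), 0.4, size=(30, 2)),
                rng.normal((0, 15), 0.4, size=(30, 2)),
            ]
        )
        assert select_k_by_silhouette(X, 2, 5, seed=0) == 3

    def test_k_min_one_starts_at_two(self):
        rng = np.random.default_rng(10)
        assert select_k_by_silhouette(two_blobs(rng), 1, 5, seed=0) == 2

    def test_k_max_bound(self):
        with pytest.raises(ValueError):
            select_k_by_silhouette(np.zeros((4, 2)), 2, 5, seed=0)


class TestRfImportance:
    def _grid(self, p):
        return WavenumberGrid(np.arange(700.0, 700.0 + p))

    def test_threshold_feature_identified(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, size=(400, 30))
        labels = (X[:, 7] > 0.5).astype(int)
        profile = rf_importance(X, labels, self._grid(30), n_trees=100, seed=0)
        assert np.argmax(profile.importance) == 7

    def test_random_labels_flat_importance(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, size=(300, 50))
        labels = rng.integers(0, 2, 300)
        profile = rf_importance(X, labels, self._grid(50), n_trees=100, seed=0)
        assert profile.importance.max() < 5.0 * profile.importance.mean()

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 1, size=(100, 20))
        labels = (X[:, 3] > 0.5).astype(int)
        profile = rf_importance(X, labels, self._grid(20), n_trees=50, seed=0)
        assert profile.importance.sum() == pytest.approx(1.0)

    def test_single_class_rejected(self):
        X = np.zeros((10, 5))
        with pytest.raises(ValueError):
            rf_importance(X, np.zeros(10, dtype=int), self._grid(5))


class TestSmoothing:
    def _profile(self, values, spacing=1.0):
        values = np.asarray(values, dtype=float)
        return ImportanceProfile(
            wavenumbers=700.0 + spacing * np.arange(values.size),
            importance=values,
        )

    def test_constant_unchanged(self):
        profile = self._profile(np.full(100, 0.01))
        out = smooth_importance(profile, window=15.0)
        np.testing.assert_allclose(out.smoothed, profile.importance, atol=1e-15)

    def test_spike_mass_conserved(self):
        values = np.zeros(200)
        values[100] = 0.37
        out = smooth_importance(self._profile(values), window=15.0)
        assert out.smoothed.sum() == pytest.approx(0.37, rel=1e-12)
        plateau = out.smoothed[out.smoothed > 0]
        assert plateau.size == 15
        np.testing.assert_allclose(plateau, 0.37 / 15, rtol=1e-9)

    def test_two_separated_spikes_keep_two_maxima(self):
        values = np.zeros(300)
        values[80] = 0.5
        values[220] = 0.5
        out = smooth_importance(self._profile(values), window=21.0)
        # independent oracle: direct convolution with a boxcar
        kernel = np.ones(21) / 21
        direct = np.convolve(values, kernel, mode="same")
        np.testing.assert_allclose(out.smoothed, direct, atol=1e-12)
        maxima = [
            i
            for i in range(1, 299)
            if out.smoothed[i] >= out.smoothed[i - 1]
            and out.smoothed[i] >= out.smoothed[i + 1]
            and out.smoothed[i] > 0
        ]
        regions = {i // 100 for i in maxima}
        assert {0, 2} <= regions

    def test_window_below_spacing_rejected(self):
        with pytest.raises(ValueError):
            smooth_importance(self._profile(np.ones(10), spacing=5.0), window=1.0)


class TestTopBands:
    def _profile_with_spikes(self, centers, heights, lo=717.0, hi=1827.0, n=1015):
        wn = np.linspace(lo, hi, n)
        values = np.zeros(n)
        for c, h in zip(centers, heights):
            values[np.argmin(np.abs(wn - c))] = h
        return ImportanceProfile(wavenumbers=wn, importance=values)

    def test_recovers_782_and_1655(self):
        profile = self._profile_with_spikes([782.0, 1655.0], [0.5, 0.4])
        profile = smooth_importance(profile, window=15.0)
        bands = top_bands(profile, n_bands=2, min_separation=50.0)
        assert np.any(np.abs(bands - 782.0) < 2.0)
        assert np.any(np.abs(bands - 1655.0) < 2.0)

    def test_monotone_profile_boundary_maximum(self):
        wn = np.linspace(700.0, 800.0, 101)
        profile = ImportanceProfile(wavenumbers=wn, importance=np.linspace(0, 1, 101))
        bands = top_bands(profile, n_bands=1, min_separation=10.0)
        assert bands.tolist() == [800.0]

    def test_close_equal_maxima_collapse(self):
        profile = self._profile_with_spikes([1000.0, 1030.0], [0.5, 0.5])
        bands = top_bands(profile, n_bands=1, min_separation=50.0)
        assert bands.size == 1
        with pytest.raises(ValueError):
            top_bands(profile, n_bands=2, min_separation=50.0)

    def test_flat_profile_single_plateau(self):
        # a constant profile is one grid-wide plateau: a single maximum
        profile = ImportanceProfile(
            wavenumbers=np.linspace(700, 800, 50), importance=np.zeros(50)
        )
        assert top_bands(profile, n_bands=1).size == 1
        with pytest.raises(ValueError):
            top_bands(profile, n_bands=2)


class TestBandFeatures:
    def test_zero_spectra(self):
        grid = WavenumberGrid(np.arange(700.0, 900.0))
        s = SpectrumSet(grid=grid, intensities=np.empty((0, len(grid))))
        feats = extract_band_features(s, [750.0, 850.0], halfwidth=5.0)
        assert feats.shape == (0, 2)

    def test_region_dominance(self, default_scan):
        feats = extract_band_features(default_scan, [782.0, 1655.0], halfwidth=5.0)
        regions = np.asarray(default_scan.truth_region)
        nucleus = feats[regions == "nucleus"]
        cytoplasm = feats[regions == "cytoplasm"]
        assert nucleus[:, 0].mean() > cytoplasm[:, 0].mean()  # 782 in nucleus
        assert cytoplasm[:, 1].mean() > nucleus[:, 1].mean()  # 1655 in cytoplasm

    def test_band_outside_grid_rejected(self, default_scan):
        with pytest.raises(ValueError):
            extract_band_features(default_scan, [100.0], halfwidth=5.0)


class TestClassifyRegions:
    def _features(self, rng, n=50):
        nuc = np.column_stack(
            [rng.normal(10, 0.5, n), rng.normal(2, 0.5, n)]
        )
        cyt = np.column_stack(
            [rng.normal(2, 0.5, n), rng.normal(10, 0.5, n)]
        )
        return np.vstack([nuc, cyt])

    def test_swapped_dominance_recovered(self):
        rng = np.random.default_rng(14)
        feats = self._features(rng)
        res = classify_regions(feats, protein_band_index=1, seed=0)
        assert set(res.molecular_labels[:50]) == {NUCLEIC_ACID_RICH}
        assert set(res.molecular_labels[50:]) == {PROTEIN_RICH}

    def test_center_spectrum_intensity_one(self):
        rng = np.random.default_rng(15)
        feats = self._features(rng)
        res = classify_regions(feats, seed=0)
        for lab in np.unique(res.labels):
            mask = res.labels == lab
            closest = np.argmin(np.where(mask, res.distance, np.inf))
            farthest = np.argmax(np.where(mask, res.distance, -np.inf))
            assert res.normalized_intensity[closest] == pytest.approx(
                res.normalized_intensity[mask].max()
            )
            assert res.normalized_intensity[farthest] == pytest.approx(0.0)

    def test_degenerate_features_rejected(self):
        with pytest.raises(ValueError):
            classify_regions(np.ones((20, 2)), seed=0)

    def test_two_columns_required(self):
        with pytest.raises(ValueError):
            classify_regions(np.zeros((10, 3)), seed=0)

    def test_order_invariance_up_to_permutation(self):
        rng = np.random.default_rng(16)
        feats = self._features(rng)
        perm = rng.permutation(len(feats))
        res1 = classify_regions(feats, seed=0)
        res2 = classify_regions(feats[perm], seed=0)
        np.testing.assert_array_equal(
            res1.molecular_labels[perm], res2.molecular_labels
        )

    def test_silhouette_attached_positive(self):
        rng = np.random.default_rng(17)
        res = classify_regions(self._features(rng), seed=0)
        assert res.sc > 0
        assert res.n == 100
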