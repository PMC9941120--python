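"""Tests for habitat identification, series extraction and contiguity."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from habitatdyn.habitats import (
    FEATURE_COLUMNS,
    HabitatSeries,
    cluster_voxels,
    compare_habitat_distributions,
    extract_series,
    inverse_zscore,
    label_clusters,
    msi_matrix,
    msi_permutation_test,
    zscore_columns,
)


def feature_frame(X):
    return pd.DataFrame(X, columns=list(FEATURE_COLUMNS))


def three_blob_frame(rng, n=50, sep=10.0):
    """Three point masses separated by `sep` SDs in every feature."""
    centers = np.array([[0, 0, 0, 0], [1, 1, 1, 1], [2, 2, 2, 2]]) * sep
    X = np.vstack([rng.normal(c, 1.0, size=(n, 4)) for c in centers])
    y = np.repeat([0, 1, 2], n)
    return feature_frame(X), y


class TestZscore:
    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        df = feature_frame(rng.lognormal(size=(200, 4)))
        std, stats = zscore_columns(df)
        np.testing.assert_allclose(std[list(FEATURE_COLUMNS)].mean(), 0, atol=1e-10)
        np.testing.assert_allclose(std[list(FEATURE_COLUMNS)].std(ddof=0), 1, atol=1e-10)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        df = feature_frame(rng.normal(5, 2, size=(100, 4)))
        std, stats = zscore_columns(df)
        back = inverse_zscore(std, stats)
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), atol=1e-12)

    def test_zero_variance_names_column(self):
        df = feature_frame(np.ones((10, 4)))
        df["ktrans"] = np.arange(10.0)
        with pytest.raises(ValueError, match="ve"):
            zscore_columns(df)


class TestClusterVoxels:
    def test_separable_blobs_perfect_partition(self):
        df, y = three_blob_frame(np.random.default_rng(2))
        std, _ = zscore_columns(df)
        labels, centers = cluster_voxels(std, seed=0)
        assert adjusted_rand_score(y, labels) == 1.0
        assert centers.shape == (3, 4)

    def test_same_seed_identical_assignment(self):
        df, _ = three_blob_frame(np.random.default_rng(3))
        std, _ = zscore_columns(df)
        a, _ = cluster_voxels(std, seed=7)
        b, _ = cluster_voxels(std, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_row_order_invariance(self):
        df, _ = three_blob_frame(np.random.default_rng(4))
        std, _ = zscore_columns(df)
        perm = np.random.default_rng(0).permutation(len(std))
        a, _ = cluster_voxels(std, seed=5)
        b, _ = cluster_voxels(std.iloc[perm].reset_index(drop=True), seed=5)
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_agglomerative_separable(self):
        df, y = three_blob_frame(np.random.default_rng(6))
        std, _ = zscore_columns(df)
        labels, _ = cluster_voxels(std, method="agglomerative")
        assert adjusted_rand_score(y, labels) == 1.0

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least k"):
            cluster_voxels(feature_frame(np.ones((2, 4))), k=3)


class TestLabelClusters:
    # cohort-mean feature vectors of the three habitats (ktrans, ve, kep, adc)
    PRINTED_MEANS = {
        "HV-HC": (0.307, 0.232, 1.625, 0.826e-3),
        "LV-HC": (0.070, 0.181, 0.447, 0.852e-3),
        "LV-LC": (0.0276, 0.848, 0.029, 0.945e-3),
    }

    def make_frame(self, order):
        rows, idx = [], []
        for i, name in enumerate(order):
            for _ in range(5):
                rows.append(self.PRINTED_MEANS[name])
                idx.append(i)
        return feature_frame(np.array(rows)), np.array(idx)

    def test_published_cluster_means_get_physiologic_labels(self):
        df, idx = self.make_frame(["HV-HC", "LV-HC", "LV-LC"])
        mapping = label_clusters(df, idx)
        assert mapping == {0: "HV-HC", 1: "LV-HC", 2: "LV-LC"}

    @pytest.mark.parametrize("order", [
        ["LV-LC", "HV-HC", "LV-HC"],
        ["LV-HC", "LV-LC", "HV-HC"],
    ])
    def test_permutation_invariance(self, order):
        df, idx = self.make_frame(order)
        mapping = label_clusters(df, idx)
        assert [mapping[i] for i in range(3)] == order

    def test_tie_raises(self):
        X = np.vstack([np.tile([0.3, 0.2, 1.0, 1e-3], (5, 1)),
                       np.tile([0.3, 0.5, 1.0, 1e-3], (5, 1)),
                       np.tile([0.1, 0.8, 0.1, 1e-3], (5, 1))])
        with pytest.raises(ValueError, match="ambiguous"):
            label_clusters(feature_frame(X), np.repeat([0, 1, 2], 5))


class TestExtractSeries:
    def make_map(self, counts):
        m = np.zeros(1000, dtype=int)
        start = 0
        for habitat, n in zip((1, 2, 3), counts):
            m[start:start + n] = habitat
            start += n
        return m.reshape(10, 10, 10)

    def test_count_times_voxel_volume(self):
        maps = [self.make_map((100, 50, 25))]
        s = extract_series(maps, [10.0], voxel_volume=0.1)
        np.testing.assert_allclose(s.volumes[0], [10.0, 5.0, 2.5])
        assert s.days[0] == 0.0  # shifted

    def test_empty_habitat_retained_and_sum_identity(self):
        maps = [self.make_map((100, 0, 25)), self.make_map((80, 10, 60))]
        s = extract_series(maps, [10.0, 12.0], voxel_volume=0.2)
        assert s.volumes[0, 1] == 0.0
        for m, vols in zip(maps, s.volumes):
            assert vols.sum() == pytest.approx((np.asarray(m) > 0).sum() * 0.2)

    def test_missing_day_errors(self):
        with pytest.raises(ValueError, match="known day"):
            extract_series([self.make_map((10, 10, 10))], [None], 0.1)


class TestMsi:
    def test_uniform_map_diagonal_one(self):
        m = np.ones((4, 4, 4), dtype=int)
        mat, score = msi_matrix(m)
        assert mat[0, 0] == 1.0
        assert score == 1.0

    def test_checkerboard_zero_diagonal(self):
        idx = np.indices((6, 6, 6)).sum(axis=0)
        board = np.where(idx % 2 == 0, 1, 2)
        mat, score = msi_matrix(board)
        assert mat[0, 0] == 0.0 and mat[1, 1] == 0.0
        assert score == 0.0

    def test_shell_phantom_beats_permutation_null(self):
        from habitatdyn.synthdata import PhantomGeometry, generate_phantom
        geom = PhantomGeometry(grid_shape=(16, 16, 16), core_radius=3,
                               band_radius=5, rim_radius=7)
        label_map, _ = generate_phantom(geom, seed=0)
        report = msi_permutation_test(label_map, n_permutations=100, seed=1)
        assert report["exceeds_null_95th"]

    def test_single_voxel_errors(self):
        m = np.zeros((3, 3, 3), dtype=int)
        m[1, 1, 1] = 1
        with pytest.raises(ValueError, match="two labelled voxels"):
            msi_matrix(m)


class TestCompareDistributions:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(10)
        X = rng.normal(1, 0.1, size=(300, 4))
        df = feature_frame(np.abs(X))
        labels = np.repeat(["HV-HC", "LV-HC", "LV-LC"], 100)
        report = compare_habitat_distributions(df, labels)
        ks = report[report.test.str.startswith("KS")]
        assert (ks.p_value > 0.05).mean() > 0.9  # allow rare chance hits

    def test_extreme_shift_is_significant(self):
        rng = np.random.default_rng(11)
        X = np.abs(rng.normal(1, 0.1, size=(300, 4)))
        labels = np.repeat(["HV-HC", "LV-HC", "LV-LC"], 100)
        X[labels == "HV-HC", 0] += 1.0  # +10 SD in ktrans
        report = compare_habitat_distributions(feature_frame(X), labels)
        ktrans_ks = report[(report.parameter == "ktrans")
                           & report.test.str.contains("HV-HC")]
        assert ktrans_ks.significant.all()

    def test_small_habitat_skipped(self):
        X = np.abs(np.random.default_rng(0).normal(1, 0.1, size=(201, 4)))
        labels = np.array(["HV-HC"] * 100 + ["LV-HC"] * 100 + ["LV-LC"])
        report = compare_habitat_distributions(feature_frame(X), labels)
        assert report.test.str.contains("skipped LV-LC").any()


class TestHabitatSeries:
    def test_invariants(self):
        with pytest.raises(ValueError, match="days\\[0\\]"):
            HabitatSeries("s", "control", [1, 2, 3, 4, 5], np.ones((5, 3)))
        with pytest.raises(ValueError, match="non-negative"):
            HabitatSeries("s", "control", [0, 1, 2, 3, 4],
                          -np.ones((5, 3)))

    def test_few_visits_flagged(self):
        s = HabitatSeries("s", "control", [0, 1], np.ones((2, 3)))
        assert "few_visits" in s.flags
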