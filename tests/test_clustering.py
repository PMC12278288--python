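import numpy as np
import pytest
from sklearn.cluster import KMeans

from themeclust.clustering import (
    elbow_curve,
    exhaustive_min_wss,
    kmeans_fit,
    rank_clusters_by_risk,
    silhouette,
)
from themeclust.data_io import IndicatorTable, ThemeSpec
from themeclust.errors import ConfigurationError, ValidationError
from themeclust.metrics import adjusted_rand_index
from themeclust.preprocessing import standardize


class TestKmeansFit:
    def test_k_equals_n_gives_zero_wss(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        model = kmeans_fit(X, k=5, seed=0, restarts=10)
        assert model.wss == pytest.approx(0.0, abs=1e-12)
        assert len(set(model.assignments)) == 5

    def test_two_tight_triads_recovered_with_exhaustive_wss(self):
        """Six 2-D points forming two tight triads 100 units apart: the
        partition must be the two triads and the WSS must equal the
        exhaustive minimum over all 2-partitions."""
        X = np.array(
            [[0, 0], [1, 0], [0, 1], [100, 100], [101, 100], [100, 101]], float
        )
        model = kmeans_fit(X, k=2, seed=0, restarts=10)
        assert len(set(model.assignments[:3])) == 1
        assert len(set(model.assignments[3:])) == 1
        assert model.assignments[0] != model.assignments[3]
        assert model.wss == pytest.approx(exhaustive_min_wss(X, 2), rel=1e-12)

    def test_duplicated_rows_double_wss_same_centers(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        X[:10, 0] += 8
        X[10:20, 1] += 8
        m1 = kmeans_fit(X, k=3, seed=3, restarts=30)
        m2 = kmeans_fit(np.vstack([X, X]), k=3, seed=3, restarts=30)
        assert m2.wss == pytest.approx(2 * m1.wss, rel=1e-9)
        c1 = np.array(sorted(m1.centers.tolist()))
        c2 = np.array(sorted(m2.centers.tolist()))
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(2).normal(size=(40, 3))
        a = kmeans_fit(X, k=3, seed=7, restarts=10)
        b = kmeans_fit(X, k=3, seed=7, restarts=10)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert a.wss == b.wss

    def test_wss_consistent_with_centers_and_assignments(self):
        X = np.random.default_rng(4).normal(size=(25, 2))
        m = kmeans_fit(X, k=4, seed=0, restarts=20)
        recomputed = ((X - m.centers[m.assignments - 1]) ** 2).sum()
        assert m.wss == pytest.approx(recomputed, rel=1e-9)
        # each point assigned to its nearest center
        from scipy.spatial.distance import cdist

        nearest = cdist(X, m.centers, "sqeuclidean").argmin(axis=1) + 1
        np.testing.assert_array_equal(nearest, m.assignments)

    @pytest.mark.parametrize("n,k", [(6, 2), (7, 3), (8, 3)])
    def test_matches_exhaustive_minimum_on_random_instances(self, n, k):
        rng = np.random.default_rng(10 * n + k)
        for _ in range(5):
            X = rng.normal(size=(n, 2))
            model = kmeans_fit(X, k=k, seed=0, restarts=50)
            assert model.wss == pytest.approx(exhaustive_min_wss(X, k), rel=1e-9, abs=1e-12)

    def test_agrees_with_sklearn_best_of_restarts(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(120, 5))
        X[:40, 0] += 4
        X[40:80, 1] += 4
        ours = kmeans_fit(X, k=3, seed=0, restarts=30)
        ref = KMeans(n_clusters=3, n_init=30, random_state=0).fit(X)
        assert ours.wss == pytest.approx(ref.inertia_, rel=1e-6)

    def test_validation_errors(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValidationError):
            kmeans_fit(X, k=4)
        with pytest.raises(ValidationError):
            kmeans_fit(X, k=0)
        with pytest.raises(ValidationError):
            kmeans_fit(np.array([[1.0, np.nan]]), k=1)


class TestElbow:
    def test_planted_three_tier_chooses_three(self, planted_dataset):
        scaled = standardize(planted_dataset.table, "zscore")
        X = scaled.theme_matrix("NAD").to_numpy()
        curve = elbow_curve(X, 1, 6, seed=0, restarts=20)
        assert curve.chosen_k == 3

    def test_single_blob_curve_nonincreasing(self):
        X = np.random.default_rng(8).normal(size=(100, 3))
        curve = elbow_curve(X, 1, 6, seed=0, restarts=20)
        assert all(b <= a + 1e-9 for a, b in zip(curve.wss_values, curve.wss_values[1:]))

    def test_two_point_range_reports_k_min_with_warning(self, caplog):
        X = np.random.default_rng(9).normal(size=(20, 2))
        import logging

        with caplog.at_level(logging.WARNING):
            curve = elbow_curve(X, 2, 3, seed=0, restarts=5)
        assert curve.chosen_k == 2
        assert len(curve.k_values) == 2

    def test_bad_range_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValidationError):
            elbow_curve(X, 3, 3)


class TestSilhouette:
    def test_separated_blobs_score_high(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(10, 0.1, (30, 2))])
        labels = np.repeat([1, 2], 30)
        assert silhouette(X, labels) > 0.9

    def test_random_split_of_one_blob_near_zero(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 2))
        labels = rng.integers(1, 3, size=80)
        assert abs(silhouette(X, labels)) < 0.15

    def test_square_corners_side_pairing_beats_diagonal(self):
        # Unit square: side pairing a=1, b in {sqrt(2), ...}; diagonal pairing
        # a=sqrt(2) > b contributions -> strictly negative.
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        side = silhouette(X, np.array([1, 1, 2, 2]))  # pairs along y
        diag = silhouette(X, np.array([1, 2, 2, 1]))  # diagonal pairs
        assert side > diag
        assert diag < 0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            silhouette(np.zeros((4, 2)), np.ones(4))


class TestRiskOrdering:
    def test_recovers_planted_worst_tier(self, planted_dataset):
        ds = planted_dataset
        scaled = standardize(ds.table, "zscore")
        for theme in ("NAD", "HAD", "HALE"):
            X = scaled.theme_matrix(theme).to_numpy()
            model = kmeans_fit(X, k=3, seed=1, restarts=20, theme=theme)
            model = rank_clusters_by_risk(model, ds.table, dict(ds.directions))
            truth = [ds.true_tiers[theme][c] for c in ds.table.countries]
            assert adjusted_rand_index(model.assignments, truth) == pytest.approx(1.0)
            # risk-ordered labels must equal the planted tiers exactly
            np.testing.assert_array_equal(model.assignments, truth)

    def test_k1_single_cluster(self):
        X = np.random.default_rng(13).normal(size=(10, 2))
        cols = ["v0", "v1"]
        import pandas as pd

        table = IndicatorTable(
            values=pd.DataFrame(X, columns=cols,
                                index=pd.Index([f"c{i}" for i in range(10)], name="country")),
            themes=(ThemeSpec("T", tuple(cols)),),
        )
        model = kmeans_fit(X, k=1, seed=0, restarts=1, theme="T")
        ranked = rank_clusters_by_risk(model, table, {"v0": 1, "v1": 1})
        assert set(ranked.assignments) == {1}

    def test_equal_severity_tie_larger_cluster_lower_label(self):
        # Two clusters symmetric about 0 in a direction-neutral pair of
        # columns (one +1, one -1) have identical severity; sizes 6 vs 4.
        import pandas as pd

        X = np.array([[x, x] for x in [-1.0] * 6 + [1.0] * 4])
        table = IndicatorTable(
            values=pd.DataFrame(X, columns=["up", "down"],
                                index=pd.Index([f"c{i}" for i in range(10)], name="country")),
            themes=(ThemeSpec("T", ("up", "down")),),
        )
        model = kmeans_fit(X, k=2, seed=0, restarts=10, theme="T")
        ranked = rank_clusters_by_risk(model, table, {"up": 1, "down": -1})
        sizes = {lbl: (ranked.assignments == lbl).sum() for lbl in (1, 2)}
        assert sizes[1] == 6 and sizes[2] == 4

    def test_missing_direction_is_configuration_error(self, planted_dataset):
        ds = planted_dataset
        model = kmeans_fit(ds.table.theme_matrix("HALE").to_numpy(), k=3, theme="HALE",
                           restarts=5)
        with pytest.raises(ConfigurationError, match="HALE_var01"):
            rank_clusters_by_risk(model, ds.table, {})

    def test_permutation_of_rows_permutes_assignments(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 3)) + np.repeat(np.eye(3), 20, axis=0) * 10
        perm = rng.permutation(60)
        a = kmeans_fit(X, k=3, seed=0, restarts=30)
        b = kmeans_fit(X[perm], k=3, seed=0, restarts=30)
        # same partition up to label names
        assert adjusted_rand_index(a.assignments[perm], b.assignments) == pytest.approx(1.0)
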