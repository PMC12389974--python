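import warnings

import numpy as np
import pandas as pd
import pytest

from netprio import prioritizer as pr
from netprio.synthetic import generate_feature_clouds


class TestCleanFeatures:
    def test_fully_observed_unchanged(self):
        df = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        out = pr.clean_features(df)
        pd.testing.assert_frame_equal(out, df)

    def test_row_with_missing_values_dropped(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((22, 14)), index=[f"G{i}" for i in range(22)])
        df.iloc[3, [0, 5, 9]] = np.nan  # 3/14 = 21.4% >= 0.5%
        out = pr.clean_features(df)
        assert "G3" not in out.index and len(out) == 21
        assert not out.isna().any().any()

    def test_sparse_column_mean_imputed_under_lax_row_rule(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((1000, 14)))
        df.iloc[[10, 20, 30, 40], 2] = np.nan  # 0.4% < 0.5% of the column
        out = pr.clean_features(df, sample_missing_max=0.5)
        assert len(out) == 1000
        col_mean = df[2].mean()
        assert out.iloc[10, 2] == pytest.approx(col_mean)

    def test_all_rows_removed_is_error(self):
        df = pd.DataFrame(np.full((3, 4), np.nan))
        with pytest.raises(ValueError, match="all rows removed"):
            pr.clean_features(df)

    def test_threshold_validation(self):
        df = pd.DataFrame(np.ones((2, 2)))
        with pytest.raises(ValueError):
            pr.clean_features(df, feature_missing_max=1.5)


class TestStandardize:
    def test_closed_form_column(self):
        out = pr.standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["x"], [-1.224744871, 0.0, 1.224744871])

    def test_constant_column_maps_to_zero(self):
        out = pr.standardize(pd.DataFrame({"x": [5.0, 5.0, 5.0], "y": [1.0, 2.0, 3.0]}))
        assert (out["x"] == 0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((30, 5)) * 100)
        once = pr.standardize(df)
        twice = pr.standardize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)

    def test_moments(self):
        rng = np.random.default_rng(3)
        out = pr.standardize(pd.DataFrame(rng.random((50, 4))))
        assert np.allclose(out.mean(), 0, atol=1e-9)
        assert np.allclose(out.std(ddof=0), 1, atol=1e-9)


class TestKMeans:
    def test_k1_centroid_is_mean_and_wcss_is_tss(self):
        rng = np.random.default_rng(4)
        X = rng.random((40, 3))
        fit = pr.kmeans(X, 1, seed=0)
        assert np.allclose(fit.centroids[0], X.mean(axis=0))
        assert fit.wcss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_two_separated_pairs_exact_partition(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        fit = pr.kmeans(X, 2, seed=0)
        assert fit.labels[0] == fit.labels[1]
        assert fit.labels[2] == fit.labels[3]
        assert fit.labels[0] != fit.labels[2]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            pr.kmeans(np.ones((3, 2)), 4)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.random((50, 4))
        a = pr.kmeans(X, 3, seed=9)
        b = pr.kmeans(X, 3, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)


class TestElbow:
    def test_recovers_three_planted_clusters(self):
        X, _ = generate_feature_clouds(n_per_cluster=50, n_clusters=3, separation=10, seed=0)
        res = pr.elbow_select_k(X, seed=0)
        assert res.chosen_k == 3
        assert not res.weak_elbow

    def test_wcss_non_increasing_in_k(self):
        rng = np.random.default_rng(6)
        X = rng.random((60, 3))
        res = pr.elbow_select_k(X, seed=1)
        ks = sorted(res.wcss)
        vals = [res.wcss[k] for k in ks]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_single_cloud_flags_weak_elbow(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 14))
        with pytest.warns(UserWarning, match="weak elbow"):
            res = pr.elbow_select_k(X, seed=1)
        assert res.weak_elbow

    def test_labels_within_chosen_k(self):
        X, _ = generate_feature_clouds(n_per_cluster=30, n_clusters=3, separation=8, seed=2)
        res = pr.elbow_select_k(X, seed=3)
        assert set(res.labels) <= set(range(res.chosen_k))


class TestIsolationForest:
    def test_planted_extreme_point_flagged(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(size=(100, 2)), [[10.0, 10.0]]])
        res = pr.isolation_forest(X, seed=0)
        assert bool(res.is_outlier.iloc[-1])
        assert res.anomaly_score.iloc[-1] == res.anomaly_score.max()

    def test_flag_count_is_ceiling_of_contamination(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(22, 14))
        res = pr.isolation_forest(X, contamination=0.10, seed=0)
        assert res.n_flagged == 3  # ceil(2.2)

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(10)
        res = pr.isolation_forest(rng.normal(size=(50, 3)), seed=1)
        assert ((res.anomaly_score > 0) & (res.anomaly_score <= 1)).all()

    def test_identical_points_tie_rule_flags_all(self):
        X = np.ones((10, 3))
        res = pr.isolation_forest(X, seed=2)
        assert res.anomaly_score.nunique() == 1
        assert res.is_outlier.all()

    def test_contamination_validation(self):
        with pytest.raises(ValueError):
            pr.isolation_forest(np.ones((10, 2)), contamination=0.6)
        with pytest.raises(ValueError):
            pr.isolation_forest(np.ones((10, 2)), contamination=0.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 5))
        a = pr.isolation_forest(X, seed=3)
        b = pr.isolation_forest(X, seed=3)
        assert (a.anomaly_score == b.anomaly_score).all()


class TestPca2:
    def test_collinear_data_explained_by_pc1(self):
        t = np.linspace(0, 1, 30)
        X = np.c_[t, 2 * t, -t]
        res = pr.pca2(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_rank2_distances_preserved(self):
        rng = np.random.default_rng(12)
        basis = rng.normal(size=(2, 6))
        coeffs = rng.normal(size=(25, 2))
        X = coeffs @ basis
        res = pr.pca2(X)
        P = res.coordinates.to_numpy()
        for i in range(0, 25, 5):
            for j in range(i + 1, 25, 5):
                d_full = np.linalg.norm(X[i] - X[j])
                d_proj = np.linalg.norm(P[i] - P[j])
                assert d_proj == pytest.approx(d_full, abs=1e-9)

    def test_variance_fractions_sorted_and_bounded(self):
        rng = np.random.default_rng(13)
        res = pr.pca2(rng.normal(size=(40, 5)))
        evr = res.explained_variance_ratio
        assert evr[0] >= evr[1] >= 0
        assert evr.sum() <= 1 + 1e-12

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(14)
        res = pr.pca2(rng.normal(size=(30, 4)))
        for c in range(2):
            j = np.abs(res.components[c]).argmax()
            assert res.components[c][j] >= 0

    def test_components_orthonormal(self):
        rng = np.random.default_rng(15)
        res = pr.pca2(rng.normal(size=(30, 4)))
        gram = res.components @ res.components.T
        assert np.allclose(gram, np.eye(2), atol=1e-9)


class TestCompositeScore:
    def test_hand_example_two_descending_indices(self):
        t = pd.DataFrame({"i1": [9.0, 5.0, 1.0], "i2": [9.0, 1.0, 5.0]},
                         index=["A", "B", "C"])
        cs = pr.composite_score(t, descending_indices=("i1", "i2"), ascending_indices=())
        assert cs.score["A"] == 1.0
        assert cs.score["B"] == 2.5
        assert cs.score["C"] == 2.5

    def test_gene_first_everywhere_scores_one(self):
        rng = np.random.default_rng(16)
        t = pd.DataFrame(rng.random((10, 3)), columns=["a", "b", "c"])
        t.iloc[0] = [10.0, 10.0, -10.0]
        cs = pr.composite_score(t, descending_indices=("a", "b"), ascending_indices=("c",))
        assert cs.score.iloc[0] == 1.0
        assert cs.rank.iloc[0] == 1.0

    def test_rank_sum_conservation(self):
        rng = np.random.default_rng(17)
        t = pd.DataFrame(rng.random((15, 4)), columns=list("abcd"))
        cs = pr.composite_score(t, descending_indices=("a", "b"), ascending_indices=("c", "d"))
        assert cs.score.mean() == pytest.approx((15 + 1) / 2)

    def test_invariant_to_monotone_transform_of_one_index(self):
        rng = np.random.default_rng(18)
        t = pd.DataFrame(rng.random((12, 3)), columns=["a", "b", "c"])
        cs1 = pr.composite_score(t, descending_indices=("a", "b"), ascending_indices=("c",))
        t2 = t.copy()
        t2["a"] = np.exp(5 * t2["a"])  # strictly increasing
        cs2 = pr.composite_score(t2, descending_indices=("a", "b"), ascending_indices=("c",))
        pd.testing.assert_series_equal(cs1.score, cs2.score)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(19)
        t = pd.DataFrame(rng.random((12, 3)), columns=["a", "b", "c"])
        cs1 = pr.composite_score(t, descending_indices=("a", "b"), ascending_indices=("c",))
        cs2 = pr.composite_score(t[["c", "a", "b"]], descending_indices=("a", "b"),
                                 ascending_indices=("c",))
        assert (cs1.score == cs2.score).all()

    def test_direction_sets_must_partition(self):
        t = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            pr.composite_score(t, descending_indices=("a",), ascending_indices=())
        with pytest.raises(ValueError):
            pr.composite_score(t, descending_indices=("a", "b"), ascending_indices=("b",))

    def test_default_direction_map_covers_all_14(self):
        assert len(pr.DESCENDING_INDICES) == 11
        assert len(pr.ASCENDING_INDICES) == 3
        assert not set(pr.DESCENDING_INDICES) & set(pr.ASCENDING_INDICES)


class TestCoreGeneRule:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["composite_rank", "is_outlier"],
                          index=[f"G{i}" for i in range(len(rows))])
        return df

    def test_outlier_within_threshold_selected(self):
        t = self._table([[5.0, 1], [1.0, 0], [21.0, 1]])
        got = pr.select_core_genes(t, 20)
        assert got.symbols == ("G0",)

    def test_ordering_by_composite_rank(self):
        t = self._table([[7.0, 1], [2.0, 1]])
        assert pr.select_core_genes(t, 20).symbols == ("G1", "G0")


class TestModelFacade:
    @pytest.fixture
    def features(self):
        rng = np.random.default_rng(20)
        from netprio.topology import CENTRALITY_COLUMNS

        X = rng.random((30, 14)) * 10
        X[:3] += 25  # three clearly extreme genes
        return pd.DataFrame(
            X, index=[f"G{i:02d}" for i in range(30)], columns=CENTRALITY_COLUMNS
        )

    def test_fit_is_deterministic(self, features):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = pr.CoreTargetModel(features).fit(seed=42)
            r2 = pr.CoreTargetModel(features).fit(seed=42)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_table_schema(self, features):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pr.CoreTargetModel(features).fit(seed=42)
        for col in ("composite_score", "composite_rank", "cluster", "anomaly_score",
                    "is_outlier", "is_core", "pc1", "pc2"):
            assert col in res.table.columns
        assert len([c for c in res.table.columns if c.startswith("rank_")]) == 14

    def test_core_flag_consistency(self, features):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pr.CoreTargetModel(features, rank_threshold=10).fit(seed=42)
        t = res.table
        expect = (t["is_outlier"] == 1) & (t["composite_rank"] <= 10)
        assert (t["is_core"] == expect).all()
        assert set(res.core_genes) == set(t.index[expect])

    def test_summary_layout(self, features):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pr.CoreTargetModel(features).fit(seed=42)
        text = res.summary()
        assert "Gene\tComposite Score" in text
        assert "chosen k" in text
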