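import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

import mplexquant as mq
from mplexquant.errors import CapacityError, ConfigurationError, ValidationError
from mplexquant.landscape import assign_rois
from mplexquant.synthetic import ClusterProfile, default_cluster_profiles


class TestSelectRois:
    def test_single_roi_in_bounds(self):
        [(r, c, s)] = mq.select_rois((3000, 3000), 1, roi_size_px=2000)
        assert 0 <= r <= 1000 and 0 <= c <= 1000 and s == 2000

    def test_roi_side_in_um(self):
        # 2000 px at 0.65 µm/px spans 1300 µm (~1.3 mm)
        assert 2000 * 0.65 == pytest.approx(1300.0)

    def test_mask_excludes_left_half(self):
        mask = np.zeros((1000, 2000), dtype=bool)
        mask[:, :1000] = True
        rois = mq.select_rois((1000, 2000), 2, roi_size_px=400,
                              artifact_mask=mask)
        assert all(c >= 1000 for _, c, _ in rois)

    def test_rois_pairwise_disjoint(self):
        rois = mq.select_rois((2000, 2000), 11, roi_size_px=400)
        assert len(rois) == 11
        for i, (r1, c1, s1) in enumerate(rois):
            for r2, c2, s2 in rois[i + 1:]:
                assert not (r1 < r2 + s2 and r2 < r1 + s1
                            and c1 < c2 + s2 and c2 < c1 + s1)

    def test_infeasible_packing_raises(self):
        with pytest.raises(CapacityError):
            mq.select_rois((900, 900), 5, roi_size_px=800)

    def test_cells_assigned_to_containing_roi(self):
        rois = [(0, 0, 100), (0, 200, 100)]
        cells = pd.DataFrame(
            {"centroid_row": [10.0, 50.0, 150.0],
             "centroid_col": [10.0, 250.0, 150.0]}
        )
        ids = assign_rois(cells, rois)
        assert list(ids) == [0, 1, -1]


class TestBuildExpressionMatrix:
    def make_cells(self, n=5):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "cell_id": np.arange(1, n + 1),
                "centroid_row": rng.uniform(0, 100, n),
                "centroid_col": rng.uniform(0, 100, n),
                "P53_nuc_mean": rng.random(n),
                "P53_cell_mean": rng.random(n),
                "P16_nuc_mean": rng.random(n),
                "P16_cell_mean": rng.random(n),
            }
        )

    def test_localization_routing(self):
        cells = self.make_cells()
        m = mq.build_expression_matrix(
            cells, ["P53", "P16"], {"P53": "nuclear", "P16": "cell"}
        )
        np.testing.assert_array_equal(m["P53"], cells["P53_nuc_mean"])
        np.testing.assert_array_equal(m["P16"], cells["P16_cell_mean"])

    def test_missing_channel_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            mq.build_expression_matrix(self.make_cells(), ["HMGB1"])

    def test_empty_roi_selection_gives_empty_matrix(self):
        cells = self.make_cells()
        cells["centroid_row"] += 1000  # outside every ROI
        m = mq.build_expression_matrix(cells, ["P53"], rois=[(0, 0, 50)])
        assert len(m) == 0


class TestClusterCells:
    def test_k1_single_cluster(self):
        x, _ = mq.sample_cluster_expression(
            default_cluster_profiles(["A", "B"]), 100, seed=0
        )
        _, labels, _, occ = mq.cluster_cells(x, k=1, seed=0)
        assert set(labels) == {0}
        assert occ.sum() == pytest.approx(1.0)
        assert occ.iloc[0] == 1.0

    def test_two_well_separated_clusters_perfect_ari(self):
        profiles = [
            ClusterProfile("lo", 0.5, {"A": 1.0, "B": 1.0}, {"A": 0.5, "B": 0.5}),
            ClusterProfile("hi", 0.5, {"A": 11.0, "B": 1.0}, {"A": 0.5, "B": 0.5}),
        ]
        x, truth = mq.sample_cluster_expression(profiles, 600, seed=1)
        _, labels, _, _ = mq.cluster_cells(x, k=2, seed=1)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_invariant_to_marker_order_and_affine_rescale(self):
        x, _ = mq.sample_cluster_expression(default_cluster_profiles(), 800,
                                            seed=2)
        markers = [c for c in x.columns if c != "cell_id"]
        _, base, _, _ = mq.cluster_cells(x, markers, k=5, seed=3)
        # permute marker columns
        perm = list(reversed(markers))
        _, permuted, _, _ = mq.cluster_cells(x[["cell_id"] + perm], perm,
                                             k=5, seed=3)
        assert adjusted_rand_score(base, permuted) == 1.0
        # affine rescale of one marker column
        y = x.copy()
        y[markers[0]] = 100.0 * y[markers[0]] - 42.0
        _, rescaled, _, _ = mq.cluster_cells(y, markers, k=5, seed=3)
        assert adjusted_rand_score(base, rescaled) == 1.0

    def test_retained_components_minimal(self):
        x, _ = mq.sample_cluster_expression(default_cluster_profiles(), 2000,
                                            seed=4)
        model, _, _, _ = mq.cluster_cells(x, var_frac=0.95, k=3, seed=4)
        cum = np.cumsum(model.explained_variance_ratio_full)
        m = model.n_components
        assert cum[m - 1] >= 0.95
        assert m == 1 or cum[m - 2] < 0.95

    def test_occurrence_sums_to_one_and_all_assigned(self):
        x, _ = mq.sample_cluster_expression(default_cluster_profiles(), 500,
                                            seed=5)
        _, labels, profile, occ = mq.cluster_cells(x, k=9, seed=5)
        assert occ.sum() == pytest.approx(1.0)
        assert len(labels) == 500
        assert profile.shape[0] == 9

    def test_k_exceeding_cells_rejected(self):
        x, _ = mq.sample_cluster_expression(
            default_cluster_profiles(["A"], diffuse_weight=0.5), 5, seed=6
        )
        with pytest.raises(ValidationError):
            mq.cluster_cells(x, k=10, seed=0)


class TestEmbed2d:
    def test_three_points_three_pairs(self):
        out = mq.embed_2d(np.random.default_rng(0).random((3, 4)), seed=0)
        assert out.shape == (3, 2)

    def test_fallback_is_first_two_components(self):
        reduced = np.random.default_rng(1).random((5, 3))
        out = mq.embed_2d(reduced, seed=0)  # n < 10 -> principal-axis fallback
        np.testing.assert_array_equal(out, reduced[:, :2])

    def test_planted_clusters_separate_in_embedding(self):
        profiles = [
            ClusterProfile("lo", 0.5, {"A": 1.0, "B": 1.0}, {"A": 0.5, "B": 0.5}),
            ClusterProfile("hi", 0.5, {"A": 11.0, "B": 11.0}, {"A": 0.5, "B": 0.5}),
        ]
        x, truth = mq.sample_cluster_expression(profiles, 300, seed=7)
        model, _, _, _ = mq.cluster_cells(x, k=2, seed=7)
        reduced = model.reduce(x[["A", "B"]].to_numpy())
        emb = mq.embed_2d(reduced, seed=7)
        assert silhouette_score(emb, truth) > 0


class TestCallPositivity:
    def make_matrix(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "cell_id": np.arange(1, n + 1),
                "Insulin": rng.normal(1, 0.3, n).clip(0),
                "Glucagon": rng.normal(1, 0.3, n).clip(0),
                "SST28": rng.normal(1, 0.3, n).clip(0),
            }
        )

    def test_all_below_threshold_all_negative(self):
        m = self.make_matrix()
        calls = mq.call_positivity(m, {"Insulin": 100.0})
        assert not calls.calls["Insulin"].any()
        assert (calls.subtype == "negative").all()

    def test_automatic_bimodal_under_1pct_error(self):
        rng = np.random.default_rng(8)
        n = 5000
        truth = rng.random(n) < 0.3
        vals = np.where(truth, rng.normal(10, 0.5, n), rng.normal(1, 0.5, n))
        m = pd.DataFrame({"cell_id": np.arange(n), "M": vals.clip(0)})
        calls = mq.call_positivity(m, {"M": "otsu"})
        err = (calls.calls["M"].to_numpy() != truth).mean()
        assert err < 0.01

    def test_single_positive_marker_routes_subtype(self):
        m = self.make_matrix()
        m.loc[0, "Glucagon"] = 50.0
        calls = mq.call_positivity(
            m, {"Insulin": 10.0, "Glucagon": 10.0, "SST28": 10.0}
        )
        assert calls.subtype.iloc[0] == "Glucagon+"
        assert (calls.subtype.iloc[1:] == "negative").all()

    def test_multi_positive_resolved_by_zscore(self):
        m = self.make_matrix()
        m.loc[0, ["Insulin", "Glucagon"]] = [20.0, 50.0]
        calls = mq.call_positivity(
            m, {"Insulin": 10.0, "Glucagon": 10.0, "SST28": 10.0}
        )
        assert calls.subtype.iloc[0] == "Glucagon+"

    def test_quantile_and_unknown_spec(self):
        m = self.make_matrix()
        calls = mq.call_positivity(m, {"Insulin": {"quantile": 0.9}})
        assert calls.calls["Insulin"].mean() == pytest.approx(0.1, abs=0.02)
        with pytest.raises(ConfigurationError):
            mq.call_positivity(m, {"Insulin": "median"})


class TestCooccurrence:
    def make_calls(self, x, y):
        calls = pd.DataFrame({"X": x, "Y": y})
        from mplexquant.landscape import PositivityCall

        return PositivityCall(calls=calls, thresholds={},
                              subtype=pd.Series(["negative"] * len(calls)))

    def test_subset_gives_fraction_one(self):
        x = np.array([True, True, False, False])
        y = np.array([True, True, True, False])
        res = mq.cooccurrence_stats(self.make_calls(x, y), "X", "Y")
        assert res.fraction == 1.0
        assert res.n_x_positive == 2

    def test_independent_planting_within_binomial_bound(self):
        rng = np.random.default_rng(9)
        n = 40_000
        x = rng.random(n) < 0.25  # ~10⁴ x-positive cells
        y = rng.random(n) < 0.3
        res = mq.cooccurrence_stats(self.make_calls(x, y), "X", "Y")
        assert 0.28 <= res.fraction <= 0.32
        assert res.ci_low < 0.3 < res.ci_high

    def test_no_positive_cells_reported_missing(self):
        x = np.zeros(10, dtype=bool)
        y = np.ones(10, dtype=bool)
        res = mq.cooccurrence_stats(self.make_calls(x, y), "X", "Y")
        assert np.isnan(res.fraction) and res.n_x_positive == 0

    def test_group_means_recovered_within_3_sem(self):
        rng = np.random.default_rng(10)
        n = 8000
        x = rng.random(n) < 0.5
        y = rng.random(n) < 0.5
        means = {(False, False): 2.0, (True, True): 3.0,
                 (True, False): 2.5, (False, True): 2.5}
        v = np.array([rng.normal(means[(a, b)], 0.5)
                      for a, b in zip(x, y)])
        res = mq.cooccurrence_stats(self.make_calls(x, y), "X", "Y",
                                    values=pd.Series(v))
        g = res.group_means.set_index("group")
        for name, key in [("X-/Y-", (False, False)), ("X+/Y+", (True, True))]:
            row = g.loc[name]
            assert abs(row["mean"] - means[key]) <= 3 * row["sem"]
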