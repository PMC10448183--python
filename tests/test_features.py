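import numpy as np
import pandas as pd
import pytest
from statsmodels.tsa.stattools import pacf as sm_pacf

import facekin as fk
from facekin.features import (
    SYMMETRIC_PAIRS,
    default_manifest,
    impute_with_medians,
)
from .conftest import make_trajectory


class TestRobustDispersion:
    def test_constant_series(self):
        assert fk.robust_dispersion(np.full(10, 3.0)) == (0.0, 0.0)

    def test_hand_computed_quartiles(self):
        iqr, mad = fk.robust_dispersion([1, 2, 3, 4, 5])
        assert iqr == pytest.approx(2.0)  # Q1=2, Q3=4 with type-7 quantiles
        assert mad == pytest.approx(1.0)

    def test_missing_values_ignored(self):
        iqr, mad = fk.robust_dispersion([1, np.nan, 2, 3, np.nan, 4, 5])
        assert (iqr, mad) == (2.0, 1.0)

    def test_all_missing_is_undefined(self):
        assert np.isnan(fk.robust_dispersion([np.nan, np.nan])).all()

    def test_mad_more_outlier_resistant_than_sd(self, rng):
        x = rng.normal(size=100)
        spiked = np.append(x, 1000.0)
        mad_change = abs(fk.robust_dispersion(spiked)[1] - fk.robust_dispersion(x)[1])
        sd_change = abs(np.std(spiked) - np.std(x))
        assert mad_change < sd_change


class TestOutlierFraction:
    def test_constant_series_has_none(self):
        assert fk.outlier_fraction(np.ones(20)) == 0.0

    def test_single_fenced_outlier(self):
        x = np.zeros(100)
        x[17] = 1000.0
        assert fk.outlier_fraction(x) == pytest.approx(0.01)

    def test_gaussian_tukey_rate(self, rng):
        # normal theory: P(outside Q1/Q3 -/+ 1.5 IQR) ~ 0.7%
        x = rng.normal(size=100_000)
        assert fk.outlier_fraction(x) == pytest.approx(0.007, abs=0.002)

    def test_too_short_is_undefined(self):
        assert np.isnan(fk.outlier_fraction([1.0, 2.0, 3.0]))


class TestPacf:
    def test_lag1_equals_biased_lag1_autocorrelation(self, rng):
        x = rng.normal(size=200).cumsum()
        d = x - x.mean()
        acf1 = (d[:-1] @ d[1:]) / (d @ d)
        assert fk.pacf_coefficient(x, 1) == pytest.approx(acf1, rel=1e-12)

    def test_matches_statsmodels_levinson_durbin(self, rng):
        x = rng.normal(size=400)
        for lag in (1, 2, 5):
            assert fk.pacf_coefficient(x, lag) == pytest.approx(
                sm_pacf(x, nlags=lag, method="ldb")[lag], rel=1e-10
            )

    def test_ar1_process_recovery(self):
        rng = np.random.default_rng(7)
        phi, n = 0.6, 5000
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal()
        assert fk.pacf_coefficient(x, 1) == pytest.approx(phi, abs=0.05)
        assert abs(fk.pacf_coefficient(x, 2)) < 0.05

    def test_white_noise_null(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=5000)
        assert abs(fk.pacf_coefficient(x, 1)) < 3 / np.sqrt(5000)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(fk.pacf_coefficient(np.ones(50), 1))


class TestSpearman:
    def test_identical_series(self, rng):
        x = rng.normal(size=30)
        assert fk.spearman_pair(x, x) == pytest.approx(1.0)

    def test_reversed_ordering(self):
        x = np.arange(10.0)
        assert fk.spearman_pair(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        b = np.array([5.0, 5.0, 3.0, 2.0, 2.0, 1.0])
        ra = pd.Series(a).rank().to_numpy()
        rb = pd.Series(b).rank().to_numpy()
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert fk.spearman_pair(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_too_few_complete_pairs_is_undefined(self):
        assert np.isnan(fk.spearman_pair([1, np.nan, 2], [np.nan, 1, 2]))


class TestBelowReference:
    def test_all_above_reference(self):
        assert fk.below_reference_fraction([2.0, 3.0, 4.0], 1.0) == 0.0

    def test_strictly_below_median_count(self):
        x = np.arange(1.0, 10.0)  # odd length, distinct
        pct = fk.below_reference_fraction(x, np.median(x))
        assert pct == pytest.approx(100.0 * 4 / 9)

    def test_own_first_quartile_near_25(self, rng):
        x = rng.uniform(size=20_000)
        assert fk.below_reference_fraction(x, np.percentile(x, 25)) == pytest.approx(
            25.0, abs=1.0
        )


class TestManifest:
    def test_default_inventory_is_649_unique_names(self):
        manifest = default_manifest()
        assert len(manifest) == 649
        assert len(set(manifest.names)) == 649

    def test_reported_model_features_present(self):
        names = set(default_manifest().names)
        for required in (
            "spearman_48_54_x",
            "spearman_48_54_y",
            "face_57_x_pacf",
            "ear_below_q1_pct",
            "face_33_angle_face30_mad",
            "face_19_x_outliers",
            "spearman_40_47_y",
        ):
            assert required in names

    def test_symmetric_pairs_are_21_disjoint_mirrors(self):
        used = [p for pair in SYMMETRIC_PAIRS for p in pair]
        assert len(SYMMETRIC_PAIRS) == 21
        assert len(set(used)) == len(used)

    def test_shipped_fixture_matches_default_inventory(self):
        from importlib import resources

        with resources.files("facekin.data").joinpath(
            "feature_manifest_v1.csv"
        ).open() as fh:
            shipped = fk.FeatureManifest.from_frame(pd.read_csv(fh))
        assert shipped.entries == default_manifest().entries

    def test_csv_round_trip(self, tmp_path):
        manifest = default_manifest()
        manifest.save_csv(tmp_path / "m.csv")
        back = fk.FeatureManifest.load_csv(tmp_path / "m.csv")
        assert back.names == manifest.names
        assert back.entries == manifest.entries


class TestFeatureVector:
    def test_vector_length_is_649(self, wiggly_trajectory):
        vec = fk.build_feature_vector(wiggly_trajectory)
        assert len(vec) == 649
        assert list(vec.index) == default_manifest().names

    def test_static_trajectory_degenerate_contract(self, template_face):
        traj = make_trajectory(np.tile(template_face, (6, 1, 1)))
        vec = fk.build_feature_vector(traj)
        iqr_like = [n for n in vec.index if n.endswith(("_iqr", "_mad", "_outliers"))]
        assert (vec[iqr_like].dropna() == 0).all()
        pacf_like = [n for n in vec.index if n.endswith("_pacf")]
        assert vec[pacf_like].isna().all()
        spearman_like = [n for n in vec.index if n.startswith("spearman_")]
        assert vec[spearman_like].isna().all()

    def test_translation_invariance(self, wiggly_trajectory):
        moved = make_trajectory(wiggly_trajectory.coords + np.array([37.0, -12.0]))
        v0 = fk.build_feature_vector(wiggly_trajectory)
        v1 = fk.build_feature_vector(moved)
        unchanged = [
            n
            for n in v0.index
            if not n.startswith("euler_")  # pose is perspective, not affine
            and (
                n.startswith(("ear_", "mar_", "spearman_", "face_33_angle_"))
                or n.endswith(("_iqr", "_mad"))
            )
        ]
        pd.testing.assert_series_equal(v0[unchanged], v1[unchanged], atol=1e-6, rtol=1e-6)

    def test_extraction_is_deterministic(self, wiggly_trajectory):
        v0 = fk.build_feature_vector(wiggly_trajectory)
        v1 = fk.build_feature_vector(wiggly_trajectory)
        assert (v0.to_numpy() == v1.to_numpy()).all()

    def test_range_invariants(self, wiggly_trajectory):
        vec = fk.build_feature_vector(wiggly_trajectory)
        disp = vec[[n for n in vec.index if n.endswith(("_iqr", "_mad", "_outliers"))]]
        assert (disp.dropna() >= 0).all()
        rho = vec[[n for n in vec.index if n.startswith("spearman_")]].dropna()
        assert rho.between(-1, 1).all()
        pct = vec[[n for n in vec.index if n.endswith("below_q1_pct")]].dropna()
        assert pct.between(0, 100).all()


class TestFeatureTable:
    def test_shape_and_column_order(self, small_table):
        table, labels = small_table
        assert table.data.shape == (15, 649)
        assert list(table.data.columns) == table.manifest.names

    def test_imputation_uses_training_medians_only(self):
        train = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [0.0, 1.0, 2.0]})
        test = pd.DataFrame({"a": [np.nan, 1e9], "b": [np.nan, 0.0]})
        filled_train, medians = impute_with_medians(train)
        filled_test, _ = impute_with_medians(test, medians)
        assert filled_train.loc[1, "a"] == 2.0
        assert filled_test.loc[0, "a"] == 2.0  # train median, not test extreme
        assert filled_test.loc[0, "b"] == 1.0

    def test_duplicate_participant_rejected(self, small_cohort):
        _, trajs, labels = small_cohort
        with pytest.raises(fk.IntegrityError):
            fk.build_feature_table([trajs[0], trajs[0]], labels)
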