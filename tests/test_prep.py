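"""Preprocessing and feature-selection pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitbalance import prep, simdata
from gaitbalance.prep import (
    cohens_d, collinearity_filter, feature_columns, group_compare,
    power_transform, replace_outliers_iqr, rf_select_features, standardize,
)
from gaitbalance.simdata import TableParams, simulate_feature_table


def _frame(**cols):
    df = pd.DataFrame(cols)
    df["subject_id"] = [f"s{i}" for i in range(len(df))]
    return df


class TestOutlierReplacement:
    def test_single_outlier_replaced_with_median(self):
        df = _frame(x=[1, 2, 3, 4, 5, 6, 7, 8, 9, 100.0])
        out, counts, mask = replace_outliers_iqr(df)
        assert counts == {"all": 1}
        assert out["x"].iloc[-1] == df["x"].median()
        assert mask["x"].sum() == 1

    def test_clean_column_untouched(self):
        df = _frame(x=np.linspace(0, 1, 12))
        out, counts, _ = replace_outliers_iqr(df)
        assert counts == {"all": 0}
        pd.testing.assert_frame_equal(out, df)

    def test_constant_column_warns_not_crashes(self):
        df = _frame(x=[2.0] * 10)
        with pytest.warns(UserWarning, match="zero IQR"):
            out, counts, _ = replace_outliers_iqr(df)
        assert counts == {"all": 0}

    def test_recovers_injected_outliers_exactly(self):
        df = simulate_feature_table(TableParams(seed=3, outlier_rate=0.05))
        injected = df.attrs["outlier_mask"].to_numpy()
        _, _, replaced = replace_outliers_iqr(df)
        assert np.array_equal(replaced.to_numpy(), injected)

    def test_fixed_point_mode_is_idempotent(self):
        """Iterated replacement reaches a fixed point; re-cleaning changes
        nothing (a single pass can cascade because the fences tighten)."""
        df = simulate_feature_table(TableParams(seed=4, outlier_rate=0.05))
        once, _, _ = replace_outliers_iqr(df, max_passes=None)
        twice, counts, _ = replace_outliers_iqr(once, max_passes=None)
        assert sum(counts.values()) == 0
        pd.testing.assert_frame_equal(once, twice)


class TestPowerTransform:
    def test_normal_feature_nearly_untouched(self):
        rng = np.random.default_rng(0)
        df = _frame(x=rng.standard_normal(4000) * 2 + 10)
        out, pt = power_transform(df)
        assert abs(pt.lambdas_[0] - 1.0) < 0.15
        assert abs(stats.skew(out["x"]) - stats.skew(df["x"])) < 0.1

    def test_lognormal_skew_removed(self):
        rng = np.random.default_rng(1)
        df = _frame(x=np.exp(rng.standard_normal(3000)))
        out, _ = power_transform(df)
        assert abs(stats.skew(out["x"])) < 0.3

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(2)
        df = _frame(x=np.exp(rng.standard_normal(300)))
        out, _ = power_transform(df)
        assert np.array_equal(np.argsort(df["x"].to_numpy()),
                              np.argsort(out["x"].to_numpy()))


class TestStandardize:
    def test_zero_mean_unit_sd(self, cohort):
        out, _ = standardize(cohort)
        for f in feature_columns(cohort):
            assert abs(out[f].mean()) < 1e-12
            assert abs(out[f].std(ddof=1) - 1.0) < 1e-12

    def test_round_trip(self, cohort):
        out, scaler = standardize(cohort)
        back = scaler.inverse(out)
        np.testing.assert_allclose(
            back[feature_columns(cohort)].to_numpy(),
            cohort[feature_columns(cohort)].to_numpy(), atol=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(_frame(x=[1.0, 1.0, 1.0]))

    def test_train_fold_parameters_apply_to_test_fold(self, cohort):
        """Fitting on one half and applying to the other leaks nothing."""
        train, test = cohort.iloc[::2], cohort.iloc[1::2]
        _, scaler = standardize(train)
        out = scaler.transform(test)
        f = feature_columns(cohort)[0]
        # test fold is NOT exactly zero-mean under train parameters
        assert abs(out[f].mean()) > 1e-6
        expected = (test[f] - train[f].mean()) / train[f].std(ddof=1)
        np.testing.assert_allclose(out[f].to_numpy(), expected.to_numpy())


class TestCollinearityFilter:
    def test_complementary_pair_resolved_by_preference(self):
        rng = np.random.default_rng(3)
        stance = rng.normal(62, 4, 80)
        df = _frame(stance_phase=stance, swing_phase=100 - stance,
                    other=rng.standard_normal(80))
        retained, dropped = collinearity_filter(
            df, keep_preferences=("stance_phase",))
        assert "stance_phase" in retained
        assert "swing_phase" not in retained
        assert dropped[0][0] == "swing_phase"

    def test_independent_features_all_retained(self):
        rng = np.random.default_rng(4)
        df = _frame(a=rng.standard_normal(300), b=rng.standard_normal(300),
                    c=rng.standard_normal(300))
        retained, dropped = collinearity_filter(df)
        assert sorted(retained) == ["a", "b", "c"]
        assert dropped == []

    def test_correlated_block_is_thinned(self):
        """A block of mutually collinear phase measures collapses to one
        survivor plus the independent features."""
        rng = np.random.default_rng(5)
        n = 200
        stance = rng.normal(62, 4, n)
        df = _frame(
            stance_phase=stance,
            swing_phase=100 - stance + rng.normal(0, 0.1, n),
            double_support=0.6 * stance + rng.normal(0, 1.0, n),
            hr=rng.standard_normal(n),
            cv=rng.standard_normal(n),
        )
        retained, _ = collinearity_filter(df, keep_preferences=("stance_phase",))
        assert "stance_phase" in retained
        assert "hr" in retained and "cv" in retained
        assert "swing_phase" not in retained and "double_support" not in retained


class TestRfSelection:
    def test_noise_feature_always_excluded(self, prepped):
        report = rf_select_features(prepped, seed=0)
        assert "noise" not in report.retained
        assert "noise" in report.excluded

    def test_shuffled_feature_is_exchangeable_with_noise(self, prepped):
        """A label-independent shuffled copy behaves like the noise baseline:
        it beats noise only at chance rate (it is exchangeable with it) and
        never outranks the genuinely discriminative indexes."""
        rng = np.random.default_rng(0)
        wins = 0
        above_informative = 0
        runs = 50
        for seed in range(runs):
            df = prepped.copy()
            df["shuffled"] = rng.permutation(df["CV_steplength"].to_numpy())
            rep = rf_select_features(df, seed=seed, cv_folds=2,
                                     n_estimators=100)
            wins += rep.importances["shuffled"] > rep.noise_importance
            above_informative += (rep.importances["shuffled"]
                                  > rep.importances["CV_steplength"])
        # exchangeability: win rate within a 99.7% binomial band around 1/2
        assert 0.29 <= wins / runs <= 0.71
        assert above_informative / runs <= 0.05

    def test_discriminative_features_beat_noise(self, prepped):
        """The three cohort-separating indexes outrank noise in >=95% of runs."""
        ok = 0
        runs = 20
        for seed in range(runs):
            rep = rf_select_features(prepped, seed=seed, n_estimators=100)
            ok += all(rep.importances[f] > rep.noise_importance
                      for f in ("CV_steplength", "sLLE_AP", "HR_AP"))
        assert ok / runs >= 0.95

    def test_single_class_errors(self, prepped):
        with pytest.raises(ValueError):
            rf_select_features(prepped[prepped["class"] == "HS"])


class TestGroupCompare:
    def test_hand_computed_d(self):
        df = _frame(x=[1.0, 2, 3, 2, 3, 4])
        df["class"] = ["pwCA"] * 3 + ["HS"] * 3
        res = group_compare(df)
        assert res.loc[0, "cohens_d"] == pytest.approx(-1.0)

    def test_identical_groups(self):
        df = _frame(x=[1.0, 2, 3, 1, 2, 3])
        df["class"] = ["pwCA"] * 3 + ["HS"] * 3
        res = group_compare(df)
        assert res.loc[0, "cohens_d"] == 0.0
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_zero_pooled_variance_errors(self):
        with pytest.raises(ValueError):
            cohens_d(np.ones(5), np.ones(5))

    def test_effect_size_recovery(self):
        """Configured standardized effect 0.8 recovered within 0.05 on
        average over 200 replicates at n=100/100."""
        means = {"pwCA": {"x": 0.8}, "HS": {"x": 0.0}}
        sds = {"pwCA": {"x": 1.0}, "HS": {"x": 1.0}}
        ds = []
        for seed in range(200):
            df = simulate_feature_table(TableParams(
                n_minority=100, n_majority=100, features=("x",),
                class_means=means, class_sds=sds, seed=seed))
            ds.append(group_compare(df).loc[0, "cohens_d"])
        assert np.mean(ds) == pytest.approx(0.8, abs=0.05)

    def test_type_one_error_near_alpha(self):
        """Under the null the t-test rejects at ~alpha (1000 replicates)."""
        means = {k: {"x": 0.0} for k in ("pwCA", "HS")}
        sds = {k: {"x": 1.0} for k in ("pwCA", "HS")}
        rej = 0
        reps = 1000
        for seed in range(reps):
            df = simulate_feature_table(TableParams(
                n_minority=12, n_majority=12, features=("x",),
                class_means=means, class_sds=sds, seed=10000 + seed))
            rej += group_compare(df).loc[0, "p"] < 0.05
        # 99.7% binomial band around 0.05 with n=1000
        assert 0.029 <= rej / reps <= 0.071


class TestLabelBlindness:
    def test_cleaning_ignores_class_labels(self, cohort):
        """Outlier handling, transform and standardisation give identical
        features when the labels are permuted."""
        rng = np.random.default_rng(9)
        shuffled = cohort.copy()
        shuffled["class"] = rng.permutation(shuffled["class"].to_numpy())
        feats = feature_columns(cohort)
        for fn in (lambda d: replace_outliers_iqr(d)[0],
                   lambda d: power_transform(d)[0],
                   lambda d: standardize(d)[0]):
            a = fn(cohort)[feats].to_numpy()
            b = fn(shuffled)[feats].to_numpy()
            np.testing.assert_array_equal(a, b)
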