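"""Split protocol, linear baseline, forest tuning, and evaluation metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import ParameterGrid

from wheatn.modeling import (
    DEFAULT_RFR_GRID,
    CVSpec,
    SplitSpec,
    compute_metrics,
    fit_rfr_cv,
    fit_slr,
    split_train_test,
)
from conftest import TINY_GRID


class TestSplit:
    def test_study_split_sizes(self, feature_table):
        train, test = split_train_test(feature_table, SplitSpec(seed=0))
        assert (len(train), len(test)) == (277, 119)
        # stratification preserves the zone proportions exactly
        assert train.zone.value_counts()["AZ1"] == 88
        assert train.zone.value_counts()["AZ2"] == 189

    def test_floor_rule_small_n(self):
        df = pd.DataFrame({"zone": ["AZ1"] * 10, "x": range(10)})
        train, test = split_train_test(df, SplitSpec(seed=1, stratify_by=None))
        assert (len(train), len(test)) == (7, 3)

    def test_partition_is_disjoint_and_exhaustive(self, feature_table):
        table = feature_table.assign(_row=np.arange(len(feature_table)))
        train, test = split_train_test(table, SplitSpec(seed=3))
        ids = sorted(train._row.tolist() + test._row.tolist())
        assert ids == list(range(len(table)))

    def test_reproducible_under_seed(self, feature_table):
        a_train, _ = split_train_test(feature_table, SplitSpec(seed=5))
        b_train, _ = split_train_test(feature_table, SplitSpec(seed=5))
        pd.testing.assert_frame_equal(a_train, b_train)

    def test_tiny_table_rejected(self):
        df = pd.DataFrame({"zone": ["AZ1"] * 5, "x": range(5)})
        with pytest.raises(ValueError):
            split_train_test(df, SplitSpec(seed=0))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.5)


class TestSLR:
    def test_recovers_exact_line(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 20)})
        df["y"] = 2.0 * df.x + 1.0
        fit = fit_slr(df, "x", "y")
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_independent_target_has_near_zero_r2(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=4000), "y": rng.normal(size=4000)})
        assert abs(fit_slr(df, "x", "y").r2) < 0.01

    def test_matches_normal_equations_on_four_points(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 5.0])
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_slr(df, "x", "y")
        # closed-form normal equations
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_zero_variance_predictor_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.raises(ValueError):
            fit_slr(df, "x", "y")


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.rmse, m.re) == (0.0, 0.0)
        assert m.r2 == 1.0

    def test_constant_offset_equals_rmse(self):
        obs = np.array([1.0, 2.0, 5.0])
        assert compute_metrics(obs, obs + 0.7).rmse == pytest.approx(0.7, abs=1e-12)

    def test_hand_computed_three_points(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 6.0])
        assert m.rmse == pytest.approx(math.sqrt(3.0), abs=1e-9)
        assert m.re == pytest.approx(100.0 * math.sqrt(3.0) / 2.0, abs=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        obs = rng.uniform(1, 5, 30)
        est = obs + rng.normal(0, 0.3, 30)
        m1 = compute_metrics(obs, est)
        m2 = compute_metrics(7.0 * obs, 7.0 * est)
        assert m2.rmse == pytest.approx(7.0 * m1.rmse, rel=1e-12)
        assert m2.re == pytest.approx(m1.re, rel=1e-12)
        assert m2.r2 == pytest.approx(m1.r2, rel=1e-12)

    def test_zero_mean_observed_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([-1.0, 1.0], [0.0, 0.0])


class TestRFR:
    def test_default_grid_has_360_combinations(self):
        assert len(list(ParameterGrid(DEFAULT_RFR_GRID))) == 360
        assert DEFAULT_RFR_GRID["n_estimators"] == [10, 60, 110, 160, 210, 260]

    def test_learns_noise_free_function_at_default_grid(self):
        # the one deliberately slow test: a full 360-point tuning sweep on a
        # small noise-free regression problem
        rng = np.random.default_rng(4)
        x = rng.uniform(-2, 2, 100)
        df = pd.DataFrame({"x": x, "z": rng.normal(size=100), "y": x + x**3})
        _, cv = fit_rfr_cv(df, ["x", "z"], "y", cv_spec=CVSpec(folds=5, seed=0))
        assert cv.r2 > 0.95

    def test_reproducible_choice_of_hyperparameters(self, feature_table):
        sub = feature_table.iloc[:100]
        grid = {"n_estimators": [20, 40], "max_depth": [3, 6],
                "min_samples_split": [2]}
        a, _ = fit_rfr_cv(sub, ["NDRE", "GDD", "BN"], "PNU", grid, CVSpec(5, 1))
        b, _ = fit_rfr_cv(sub, ["NDRE", "GDD", "BN"], "PNU", grid, CVSpec(5, 1))
        assert a.best_params == b.best_params
        assert np.allclose(a.importances, b.importances)

    def test_cv_folds_partition_training_rows(self):
        spec = CVSpec(folds=5, seed=2)
        seen = np.zeros(37, dtype=int)
        for _, va in spec.kfold().split(np.zeros((37, 1))):
            seen[va] += 1
        assert (seen == 1).all()

    def test_beats_constant_mean_predictor_on_train(self, feature_table):
        sub = feature_table.iloc[:100]
        result, _ = fit_rfr_cv(sub, ["NDRE", "BN"], "AGB", TINY_GRID, CVSpec(3, 0))
        rmse_model = result.evaluate(sub).rmse
        rmse_const = compute_metrics(
            sub.AGB, np.full(len(sub), sub.AGB.mean())
        ).rmse
        assert rmse_model <= rmse_const

    def test_empty_grid_list_rejected(self, feature_table):
        with pytest.raises(ValueError):
            fit_rfr_cv(feature_table, ["NDRE"], "AGB",
                       {"n_estimators": []}, CVSpec(3, 0))

    def test_no_predictors_rejected(self, feature_table):
        with pytest.raises(ValueError):
            fit_rfr_cv(feature_table, [], "AGB", TINY_GRID, CVSpec(3, 0))
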