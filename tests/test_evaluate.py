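import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prognet as pn
from prognet.evaluate import (
    binary_metrics,
    calibration_bins,
    continuous_metrics,
    internal_cross_validation,
    prediction_correlations,
    severity_category_remission,
)
from prognet.models import fit_null, model_spec


class TestContinuousMetrics:
    def test_perfect_prediction(self):
        m = continuous_metrics([1, 2, 3], [1, 2, 3])
        assert m.r_squared == 1.0 and m.rmse == 0.0 and m.mae == 0.0

    def test_worked_arithmetic(self):
        m = continuous_metrics([10, 20, 30], [12, 18, 33])
        assert m.r_squared == pytest.approx(1 - 17 / 200)
        assert m.rmse == pytest.approx(np.sqrt(17 / 3))
        assert m.mae == pytest.approx(7 / 3)

    def test_miscentred_constant_goes_negative(self):
        m = continuous_metrics([10, 20, 30], [15, 15, 15])
        assert m.r_squared == pytest.approx(-0.375)

    def test_constant_observed_flagged(self):
        m = continuous_metrics([5, 5, 5], [4, 5, 6])
        assert m.r_squared is None
        assert "constant_observed_r2_undefined" in m.flags

    @given(st.lists(st.tuples(st.floats(0, 63), st.floats(0, 63)),
                    min_size=2, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_rmse_dominates_mae(self, pairs):
        y, yhat = zip(*pairs)
        m = continuous_metrics(list(y), list(yhat))
        assert m.rmse >= m.mae - 1e-9  # equality case up to rounding
        assert m.mae >= 0


class TestBinaryMetrics:
    def test_worked_auc(self):
        m = binary_metrics([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert m.auc == pytest.approx(0.75)

    def test_worked_brier(self):
        m = binary_metrics([1, 0], [0.8, 0.3])
        assert m.brier == pytest.approx(0.065)

    def test_constant_probability_auc_half(self):
        m = binary_metrics([0, 1, 0, 1], [0.4, 0.4, 0.4, 0.4])
        assert m.auc == pytest.approx(0.5)

    def test_single_class_flagged(self):
        m = binary_metrics([1, 1, 1], [0.2, 0.5, 0.9])
        assert m.auc is None and "single_class_auc_undefined" in m.flags
        assert m.brier is not None


def test_null_model_r2_never_positive():
    """A constant prediction can never beat the evaluation-set mean, so the
    null model's R^2 is <= 0 on any evaluation set."""
    rng = np.random.default_rng(21)
    for _ in range(100):
        y_train = rng.normal(15, 8, 50)
        y_eval = rng.normal(rng.uniform(5, 25), 8, 40)
        null = fit_null(y_train, "gaussian")
        m = continuous_metrics(y_eval, np.full_like(y_eval, null.null_value))
        assert m.r_squared <= 1e-12


class TestCalibrationBins:
    def test_bin_partition_120_by_50(self):
        rng = np.random.default_rng(1)
        y, yhat, rem = rng.normal(size=120), rng.normal(size=120), rng.integers(0, 2, 120)
        cb = calibration_bins(y, yhat, rem, bin_size=50)
        assert list(cb.bin_counts) == [50, 50, 20]
        assert cb.partial_last_bin

    def test_perfect_calibration(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=100)
        cb = calibration_bins(y, y, np.zeros(100), bin_size=25)
        np.testing.assert_allclose(cb.mean_predicted, cb.mean_observed)
        assert not cb.partial_last_bin

    def test_bin_size_one_reproduces_sorted_pairs(self):
        y = np.array([3.0, 1.0, 2.0])
        yhat = np.array([30.0, 10.0, 20.0])
        cb = calibration_bins(y, yhat, np.zeros(3), bin_size=1)
        np.testing.assert_allclose(cb.mean_predicted, [10, 20, 30])
        np.testing.assert_allclose(cb.mean_observed, [1, 2, 3])


class TestSeverityCategories:
    @pytest.mark.parametrize("pred, cat", [
        (13, "minimal"), (14, "mild"), (19, "mild"), (20, "moderate"),
        (28, "moderate"), (29, "severe"), (13.4, "minimal"), (13.6, "mild"),
    ])
    def test_boundaries(self, pred, cat):
        table = severity_category_remission([pred], [1.0])
        row = table.to_frame().set_index("category")
        assert row.loc[cat, "n"] == 1
        assert row["n"].sum() == 1

    def test_all_minimal_half_remitted(self):
        rem = [1, 0] * 5
        table = severity_category_remission([5.0] * 10, rem)
        frame = table.to_frame().set_index("category")
        assert frame.loc["minimal", "n"] == 10
        assert frame.loc["minimal", "remission_fraction"] == 0.5
        assert frame.loc["mild", "n"] == 0
        assert np.isnan(frame.loc["mild", "remission_fraction"])

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            table = severity_category_remission([-3.0, 70.0], [0.0, 0.0])
        assert table.counts.sum() == 2


class TestPredictionCorrelations:
    def test_affine_invariance_and_self(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=50)
        corr = prediction_correlations({1: a, 2: 2 * a + 3, 3: -a})
        assert corr.loc[1, 1] == pytest.approx(1.0)
        assert corr.loc[1, 2] == pytest.approx(1.0)
        assert corr.loc[1, 3] == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="constant"):
            corr = prediction_correlations({1: rng.normal(size=20), 9: np.full(20, 5.0)})
        assert np.isnan(corr.loc[9, 1])


class TestInternalCrossValidation:
    def small_tables(self, noise_sd, seed=13, n=120):
        cfg = dataclasses.replace(
            pn.default_cohort_config(seed=seed),
            n_studies_test=0, n_per_study=[n, n], n_studies_train=2,
            missing_rate=0.0, outcome_noise_sd=noise_sd,
        )
        return pn.generate_multi_study(cfg)

    def test_noise_free_outcome_recovered(self):
        """With a noise-free linear outcome, CV of the plain sum-score OLS
        model explains nearly everything that isn't thresholding error."""
        cfg = dataclasses.replace(
            pn.default_cohort_config(seed=13),
            n_studies_test=0, n_per_study=[150, 150], n_studies_train=2,
            missing_rate=0.0, outcome_noise_sd=0.0,
            # outcome driven by the observable auxiliary totals only
            outcome_coefficients=[5.0, 0.0, 1.0, 2.0, 1.0],
        )
        tables = pn.generate_multi_study(cfg)
        ms = internal_cross_validation(tables, model_spec(6, "continuous"),
                                       folds=5, seed=0)
        assert ms.r_squared > 0.99

    def test_pure_noise_outcome_r2_nonpositive_in_median(self):
        r2s = []
        for seed in range(7):
            cfg = dataclasses.replace(
                pn.default_cohort_config(seed=seed),
                n_studies_test=0, n_per_study=[100, 100], n_studies_train=2,
                missing_rate=0.0, outcome_noise_sd=10.0, study_mean_shift_sd=0.0,
                outcome_coefficients=[15.0, 0.0, 0.0, 0.0, 0.0],
            )
            tables = pn.generate_multi_study(cfg)
            ms = internal_cross_validation(tables, model_spec(6, "continuous"),
                                           folds=5, seed=seed)
            r2s.append(ms.r_squared)
        assert np.median(r2s) <= 0

    def test_same_seed_identical(self):
        tables = self.small_tables(noise_sd=8.0)
        a = internal_cross_validation(tables, model_spec(6, "continuous"), folds=4, seed=3)
        b = internal_cross_validation(tables, model_spec(6, "continuous"), folds=4, seed=3)
        assert a.r_squared == b.r_squared and a.rmse == b.rmse
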