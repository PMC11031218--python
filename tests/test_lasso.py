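import math

import numpy as np
import pandas as pd
import pytest

from responderomics.errors import ConfigError, DataError, DesignError
from responderomics.io_formats import SampleSheet
from responderomics.lasso_stability import (
    cv_lambda,
    fit_path,
    lambda_path,
    lasso_fit,
    model_success,
    split_cohort,
    stability_run,
    standardize,
    top_markers,
)


def _design(rng, n=20, p=8, signal=None):
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"g{j}" for j in range(p)],
    )
    if signal is None:
        y = pd.Series(rng.normal(size=n), index=X.index)
    else:
        y = pd.Series(X.to_numpy() @ signal + 0.1 * rng.normal(size=n), index=X.index)
    return standardize(X, y), X, y


class TestStandardize:
    def test_stated_convention_on_small_column(self):
        X = pd.DataFrame({"g": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        y = pd.Series([0.0, 1.0, 0.0, 1.0], index=list("abcd"))
        d = standardize(X, y)
        assert d.x_mean[0] == pytest.approx(2.5)
        assert d.x_scale[0] == pytest.approx(math.sqrt(1.25))

    def test_columns_have_zero_mean_unit_variance(self, rng):
        d, _, _ = _design(rng)
        assert np.abs(d.X.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose((d.X**2).mean(axis=0), 1.0, rtol=1e-12)
        assert abs(d.y.mean()) < 1e-12

    def test_constant_gene_dropped_all_constant_rejected(self, rng):
        X = pd.DataFrame(
            {"flat": np.ones(10), "ok": rng.normal(size=10)},
            index=[f"s{i}" for i in range(10)],
        )
        y = pd.Series(rng.normal(size=10), index=X.index)
        d = standardize(X, y)
        assert d.dropped == ["flat"] and d.gene_ids == ["ok"]
        with pytest.raises(DataError):
            standardize(X[["flat"]], y)

    def test_back_mapped_coefficients_reproduce_predictions(self, rng):
        d, X, y = _design(rng, signal=np.array([1.0, -2.0, 0, 0, 0, 0, 0, 0.5]))
        fit = lasso_fit(d, 0.01)
        pred_std = fit.predict_std(d.X, d.y_mean)
        pred_orig = fit.intercept + X.to_numpy() @ fit.coef
        np.testing.assert_allclose(pred_orig, pred_std, atol=1e-10)


class TestLassoFit:
    def test_lambda_at_or_above_max_gives_zero_model(self, rng):
        d, _, _ = _design(rng)
        lam_max = lambda_path(d)[0]
        for lam in (lam_max, 2 * lam_max):
            assert np.all(lasso_fit(d, lam).coef_std == 0.0)

    def test_single_predictor_closed_form(self, rng):
        X = pd.DataFrame({"g": rng.normal(size=15)}, index=[f"s{i}" for i in range(15)])
        y = pd.Series(rng.normal(size=15), index=X.index)
        d = standardize(X, y)
        rho = float(d.X[:, 0] @ d.y) / d.n
        for lam in (0.0, abs(rho) / 2, abs(rho) * 2):
            expected = math.copysign(max(abs(rho) - lam, 0.0), rho)
            assert lasso_fit(d, lam).coef_std[0] == pytest.approx(expected, abs=1e-12)

    def test_unpenalized_limit_matches_least_squares(self, rng):
        d, _, _ = _design(rng, n=30, p=5)
        fit = lasso_fit(d, 0.0)
        ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef_std, ols, atol=1e-8)

    def test_kkt_conditions_on_random_fits(self, rng):
        for _ in range(5):
            d, _, _ = _design(rng, n=12, p=30)
            lam = float(rng.uniform(0.01, 0.5)) * lambda_path(d)[0]
            fit = lasso_fit(d, lam)
            assert fit.converged
            assert fit.kkt_violation <= 1e-6

    def test_deterministic_given_design_and_lambda(self, rng):
        d, _, _ = _design(rng)
        a = lasso_fit(d, 0.05)
        b = lasso_fit(d, 0.05)
        np.testing.assert_array_equal(a.coef_std, b.coef_std)


class TestLambdaPath:
    def test_length_and_strict_decrease(self, rng):
        d, _, _ = _design(rng)
        path = lambda_path(d, n_lambda=100)
        assert len(path) == 100
        assert (np.diff(path) < 0).all()

    def test_lambda_max_matches_column_scan(self, rng):
        d, _, _ = _design(rng)
        brute = max(abs(float(d.X[:, j] @ d.y)) / d.n for j in range(d.p))
        assert lambda_path(d)[0] == pytest.approx(brute, rel=1e-12)

    def test_zero_outcome_gives_degenerate_path(self):
        X = pd.DataFrame({"g": [1.0, 2.0, 3.0]}, index=list("abc"))
        y = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        d = standardize(X, y)
        np.testing.assert_array_equal(lambda_path(d), [0.0])

    def test_path_coefficients_change_continuously(self, rng):
        d, _, _ = _design(rng, n=15, p=10, signal=np.arange(10) / 5.0)
        path = lambda_path(d)
        betas = fit_path(d, path)
        assert np.abs(np.diff(betas, axis=0)).max() < 0.5


class TestCvLambda:
    def test_same_seed_same_choice(self, rng):
        d, _, _ = _design(rng)
        assert cv_lambda(d, seed=7) == cv_lambda(d, seed=7)

    def test_noise_outcome_prefers_strong_penalty(self):
        upper = 0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            d, _, _ = _design(r, n=20, p=30)
            path = lambda_path(d)
            lam = cv_lambda(d, seed=seed)
            upper += lam >= path[len(path) // 2]
        assert upper >= 16  # >= 80% of seeds in the upper half of the path

    def test_strong_predictor_survives_selection(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(200 + seed)
            signal = np.zeros(8)
            signal[3] = 3.0
            d, _, _ = _design(r, n=40, p=8, signal=signal)
            lam = cv_lambda(d, seed=seed)
            fit = lasso_fit(d, lam)
            hits += fit.coef_std[3] != 0.0
        assert hits >= 19

    def test_too_many_folds_rejected(self, rng):
        d, _, _ = _design(rng, n=4)
        with pytest.raises(ConfigError):
            cv_lambda(d, k=5)


class TestSplitCohort:
    def test_seven_eleven_cohort_splits_nine_nine(self, small_sheet):
        for seed in range(10):
            train, test = split_cohort(small_sheet, seed)
            assert len(train) == 9 and len(test) == 9
            groups = small_sheet.subject_group()
            for side in (train, test):
                assert {groups[s] for s in side} == {"LRE", "RES"}

    def test_partition_disjoint_and_exhaustive(self, small_sheet):
        train, test = split_cohort(small_sheet, 3)
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(small_sheet.subjects)

    def test_same_seed_same_split(self, small_sheet):
        assert split_cohort(small_sheet, 42) == split_cohort(small_sheet, 42)

    def test_tiny_group_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a_w0", "b_w0", "c_w0"],
                "subject_id": ["a", "b", "c"],
                "group": ["LRE", "RES", "RES"],
                "timepoint": ["w0"] * 3,
                "sex": ["F", "M", "F"],
            }
        )
        with pytest.raises(DesignError):
            split_cohort(SampleSheet(df), 0)


class TestModelSuccess:
    def test_half_within_band_is_successful(self):
        ok, within = model_success(
            np.array([1.0, 1.0, 1.0, 1.0]), np.array([1.05, 0.95, 1.2, 1.2])
        )
        assert ok
        assert within.tolist() == [True, True, False, False]

    def test_just_outside_ten_percent_band(self):
        ok, within = model_success(np.array([2.0]), np.array([2.21]))
        assert not ok
        assert within.tolist() == [False]

    def test_exact_predictions_successful(self):
        y = np.array([0.8, 1.3, 1.0])
        ok, within = model_success(y, y.copy())
        assert ok and within.all()

    def test_empty_test_set_rejected(self):
        with pytest.raises(DataError):
            model_success(np.array([]), np.array([]))


class TestStabilityRun:
    def test_same_master_seed_reproduces_result_exactly(self, baseline_design, small_sheet):
        X, y = baseline_design
        a = stability_run(X, y, small_sheet, n_iter=8, master_seed=5)
        b = stability_run(X, y, small_sheet, n_iter=8, master_seed=5)
        pd.testing.assert_frame_equal(a.gene_table, b.gene_table)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)
        assert a.n_successful == b.n_successful

    def test_counts_come_from_successful_models_only(self, baseline_design, small_sheet):
        X, y = baseline_design
        res = stability_run(X, y, small_sheet, n_iter=30, master_seed=2)
        per_iter = res.iterations
        n_succ = int(per_iter["success"].sum())
        assert res.n_successful == n_succ
        assert res.gene_table["selection_count"].max() <= n_succ

    def test_frequencies_bounded(self, baseline_design, small_sheet):
        X, y = baseline_design
        res = stability_run(X, y, small_sheet, n_iter=20, master_seed=9)
        f = res.gene_table["frequency_percent"]
        assert ((f >= 0) & (f <= 100)).all()


class TestTopMarkers:
    def _result(self):
        from responderomics.lasso_stability import StabilityResult

        tab = pd.DataFrame(
            {
                "selection_count": [8, 6, 6, 1],
                "frequency_percent": [80.0, 60.0, 60.0, 10.0],
                "mean_abs_coef": [0.9, 0.2, 0.5, 0.01],
            },
            index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
        )
        return StabilityResult(10, 10, tab, pd.DataFrame())

    def test_frequency_then_coefficient_tie_break(self):
        ranked = top_markers(self._result(), n=4)
        assert list(ranked.index) == ["g1", "g3", "g2", "g4"]

    def test_n_larger_than_gene_count_returns_full_ranking(self):
        assert len(top_markers(self._result(), n=100)) == 4

    def test_ranking_invariant_under_column_permutation(self):
        res = self._result()
        perm = res.gene_table.iloc[[2, 0, 3, 1]]
        from responderomics.lasso_stability import StabilityResult

        res_perm = StabilityResult(10, 10, perm, pd.DataFrame())
        assert list(top_markers(res, 4).index) == list(top_markers(res_perm, 4).index)

    def test_no_successful_models_is_explicit_error(self):
        res = self._result()
        res.n_successful = 0
        with pytest.raises(DataError, match="no successful models"):
            top_markers(res)
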