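"""Ridge prediction machinery: grid, features, residualization, leakage."""

import numpy as np
import pytest

from pfntopo.prediction import (PredictionConfig, inner_select_lambda,
                                make_lambda_grid, per_network_accuracy,
                                permutation_null, prepare_features,
                                repeated_random_2fcv, residualize_covariates,
                                ridge_fit, run_nested_2fcv,
                                sum_weights_by_network)
from tests.conftest import outcome_and_covariates


class TestLambdaGrid:
    def test_sixteen_ascending_powers_of_two(self):
        grid = make_lambda_grid()
        assert grid.size == 16
        assert grid[0] == 2.0**-10 == pytest.approx(9.765625e-4)
        assert grid[-1] == 2.0**5
        np.testing.assert_allclose(grid[1:] / grid[:-1], 2.0)


class TestPrepareFeatures:
    def test_concatenation_order(self):
        rng = np.random.default_rng(0)
        loadings = [rng.random((3, 5)) for _ in range(4)]
        X = prepare_features(loadings)
        assert X.shape == (4, 15)
        np.testing.assert_array_equal(X[2, 5:10], loadings[2][1])

    def test_single_network(self):
        rng = np.random.default_rng(1)
        loadings = [rng.random((3, 5)) for _ in range(2)]
        X = prepare_features(loadings, [1])
        assert X.shape == (2, 5)
        np.testing.assert_array_equal(X[0], loadings[0][1])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            prepare_features([np.ones((2, 3)), np.ones((2, 4))])


class TestResidualize:
    def test_orthogonal_outcome_unchanged(self):
        rng = np.random.default_rng(2)
        n = 500
        cov = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        # orthogonalize against the training-fold design: coefficients vanish
        Dtr = np.column_stack([np.ones(250), cov[:250]])
        y[:250] -= Dtr @ np.linalg.lstsq(Dtr, y[:250], rcond=None)[0]
        ya, yb = residualize_covariates(y[:250], y[250:], cov[:250], cov[250:])
        np.testing.assert_allclose(ya, y[:250], atol=1e-6)
        np.testing.assert_allclose(yb, y[250:], atol=1e-6)

    def test_exact_linear_outcome_zeroed(self):
        rng = np.random.default_rng(3)
        cov = rng.standard_normal((50, 2))
        y = 2.0 + cov @ np.array([1.5, -0.5])
        ya, yb = residualize_covariates(y[:25], y[25:], cov[:25], cov[25:])
        np.testing.assert_allclose(ya, 0, atol=1e-8)
        np.testing.assert_allclose(yb, 0, atol=1e-8)

    def test_no_leakage_from_test_outcomes(self):
        rng = np.random.default_rng(4)
        cov = rng.standard_normal((60, 2))
        y = rng.standard_normal(60)
        _, adj1 = residualize_covariates(y[:30], y[30:], cov[:30], cov[30:])
        yperm = y.copy()
        yperm[30:] = y[30:][rng.permutation(30)]
        _, adj2 = residualize_covariates(yperm[:30], yperm[30:],
                                         cov[:30], cov[30:])
        # the adjustment applied to each test subject depends only on its
        # covariates and the training coefficients
        np.testing.assert_allclose(y[30:] - adj1, yperm[30:] - adj2)

    def test_rank_deficient_design(self):
        cov = np.ones((10, 2))
        with pytest.raises(ValueError):
            residualize_covariates(np.ones(10), np.ones(5), cov, cov[:5])


class TestRidgeFit:
    def test_lambda_zero_matches_least_squares(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 6))
        y = rng.standard_normal(50)
        fit = ridge_fit(X, y, 0.0)
        Z = (X - X.mean(0)) / X.std(0)
        D = np.column_stack([np.ones(50), Z])
        coef = np.linalg.lstsq(D, y, rcond=None)[0]
        np.testing.assert_allclose(fit.weights, coef[1:], atol=1e-8)
        np.testing.assert_allclose(fit.predict(X), D @ coef, atol=1e-8)

    def test_shrinkage_limit(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30) + 5
        fit = ridge_fit(X, y, 1e12)
        assert np.abs(fit.weights).max() < 1e-6
        np.testing.assert_allclose(fit.predict(X), y.mean(), atol=1e-5)

    def test_duplicated_columns_share_weight(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        X = np.column_stack([x, x + 0.0, rng.standard_normal(40)])
        fit = ridge_fit(X, rng.standard_normal(40), 1.0)
        assert fit.weights[0] == pytest.approx(fit.weights[1], rel=1e-8)

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.full(20, 3.0), rng.standard_normal(20)])
        fit = ridge_fit(X, rng.standard_normal(20), 1.0)
        np.testing.assert_array_equal(fit.kept, [False, True])


class TestInnerSelection:
    def test_dominant_lambda_selected(self):
        # strong signal, tiny noise: small lambda dominates both r and MAE
        rng = np.random.default_rng(9)
        X = rng.standard_normal((80, 5))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0, 0.0]) + 0.01 * rng.standard_normal(80)
        grid = make_lambda_grid()
        lam, trace = inner_select_lambda(X, y, grid, seed=0)
        assert lam == grid[np.argmax(trace.score)]
        best_r = np.argmax(trace.mean_r)
        best_mae = np.argmin(trace.mean_mae)
        if best_r == best_mae:  # dominance forces that grid point
            assert lam == grid[best_r]

    def test_selection_deterministic(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((40, 10))
        y = rng.standard_normal(40)
        grid = make_lambda_grid()
        assert inner_select_lambda(X, y, grid, seed=3)[0] == \
            inner_select_lambda(X, y, grid, seed=3)[0]

    def test_regularization_chosen_with_many_features(self, loadings_cohort):
        subjects, truth, _ = loadings_cohort
        X = prepare_features(truth.true_loadings)
        y, _ = outcome_and_covariates(subjects)
        chosen = [inner_select_lambda(X[:100], y[:100], make_lambda_grid(),
                                      seed=s)[0] for s in range(10)]
        assert all(lam > 0 for lam in chosen)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            inner_select_lambda(np.ones((3, 2)), np.ones(3),
                                make_lambda_grid())


class TestNestedCV:
    def test_planted_signal_predicts(self, loadings_cohort):
        subjects, truth, _ = loadings_cohort
        X = prepare_features(truth.true_loadings)
        y, cov = outcome_and_covariates(subjects)
        ra, rb = run_nested_2fcv(X[:100], y[:100], X[100:], y[100:],
                                 covariates_a=cov[:100],
                                 covariates_b=cov[100:], seed=0)
        assert ra.r > 0.3 and rb.r > 0.3
        assert ra.mae >= 0 and rb.chosen_lambda in make_lambda_grid()

    def test_deterministic(self, loadings_cohort):
        subjects, truth, _ = loadings_cohort
        X = prepare_features(truth.true_loadings)
        y, cov = outcome_and_covariates(subjects)
        r1 = run_nested_2fcv(X[:100], y[:100], X[100:], y[100:],
                             covariates_a=cov[:100], covariates_b=cov[100:],
                             seed=11)
        r2 = run_nested_2fcv(X[:100], y[:100], X[100:], y[100:],
                             covariates_a=cov[:100], covariates_b=cov[100:],
                             seed=11)
        assert r1[0].r == r2[0].r and r1[1].r == r2[1].r
        np.testing.assert_array_equal(r1[0].predictions, r2[0].predictions)

    def test_fitted_model_ignores_test_outcomes(self, loadings_cohort):
        subjects, truth, _ = loadings_cohort
        X = prepare_features(truth.true_loadings)
        y, cov = outcome_and_covariates(subjects)
        rng = np.random.default_rng(12)
        yp = y.copy()
        yp[100:] = y[100:][rng.permutation(100)]
        r1 = run_nested_2fcv(X[:100], y[:100], X[100:], y[100:],
                             covariates_a=cov[:100], covariates_b=cov[100:],
                             seed=5)
        r2 = run_nested_2fcv(X[:100], yp[:100], X[100:], yp[100:],
                             covariates_a=cov[:100], covariates_b=cov[100:],
                             seed=5)
        # direction A->B trains on sample A only: identical predictions
        np.testing.assert_allclose(r1[0].predictions, r2[0].predictions)


class TestRepeatsAndPermutations:
    def test_repeat_count(self, loadings_cohort):
        subjects, truth, _ = loadings_cohort
        X = prepare_features(truth.true_loadings, [0])
        y, cov = outcome_and_covariates(subjects)
        cfg = PredictionConfig(n_repeats=7, seed=2)
        acc = repeated_random_2fcv(X, y, cfg, covariates=cov)
        assert acc.shape == (7, 2)

    def test_permutation_p_floor(self, loadings_cohort):
        subjects, truth, _ = loadings_cohort
        X = prepare_features(truth.true_loadings)
        y, cov = outcome_and_covariates(subjects)
        cfg = PredictionConfig(n_perm=19, seed=3)
        null = permutation_null(X[:100], y[:100], X[100:], y[100:], cfg,
                                cov[:100], cov[100:])
        assert null.null_accuracies.size == 19
        # strong planted signal beats every null permutation
        assert null.p_value == pytest.approx(1 / 20)

    def test_per_network_identifies_planted_network(self, loadings_cohort):
        subjects, truth, _ = loadings_cohort
        y, cov = outcome_and_covariates(subjects)
        la = truth.true_loadings[:100]
        lb = truth.true_loadings[100:]
        reports = per_network_accuracy(la, y[:100], lb, y[100:],
                                       covariates_a=cov[:100],
                                       covariates_b=cov[100:])
        assert len(reports) == 6
        mean_r = [0.5 * (a.r + b.r) for a, b in reports]
        assert int(np.argmax(mean_r)) == 0  # coupling planted on network 0


class TestWeightSummaries:
    def test_block_sums(self):
        rng = np.random.default_rng(13)
        loadings = [rng.random((3, 4)) for _ in range(30)]
        X = prepare_features(loadings)
        y = X[:, 5] + 0.1 * rng.standard_normal(30)  # block 1 carries signal
        fit = ridge_fit(X, y, 0.5)
        signed, absolute = sum_weights_by_network(fit, 3, 4)
        assert signed.shape == (3,)
        assert absolute[1] == np.max(absolute)
        assert signed.sum() == pytest.approx(fit.weights.sum())
        assert np.all(absolute >= np.abs(signed) - 1e-12)

    def test_zero_weights(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((20, 6))
        fit = ridge_fit(X, rng.standard_normal(20), 1e12)
        signed, absolute = sum_weights_by_network(fit, 2, 3)
        np.testing.assert_allclose(absolute, 0, atol=1e-5)

    def test_block_mismatch(self):
        rng = np.random.default_rng(15)
        fit = ridge_fit(rng.standard_normal((20, 6)), rng.standard_normal(20), 1.0)
        with pytest.raises(ValueError):
            sum_weights_by_network(fit, 4, 2)
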