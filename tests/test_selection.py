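import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.linear_model import Lasso

import helpers
from multicna.io import ResponseVector
from multicna.selection import (
    MarkerSelectionModel,
    coefficients_at_lambda,
    cv_select_lambda,
    lars_lasso_path,
    lasso_objective,
    logistic_lambda_max,
    logistic_lasso,
    select_markers,
)


class TestObjective:
    def test_zero_beta_is_sum_of_squares(self, rng):
        y = rng.normal(size=10)
        X = rng.normal(size=(10, 4))
        assert lasso_objective(X, y, np.zeros(4), 3.0) == pytest.approx((y ** 2).sum())

    def test_lambda_zero_matches_ols_rss(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        assert lasso_objective(X, y, beta, 0.0) == pytest.approx(rss)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            lasso_objective(rng.normal(size=(5, 3)), np.zeros(5), np.zeros(4), 1.0)


class TestLarsPath:
    def test_beta_zero_at_and_above_lambda_max(self, rng):
        X = rng.normal(size=(15, 40))
        y = rng.normal(size=15)
        path = lars_lasso_path(X, y)
        lam_max = path.lambdas[0]
        # lambda_max = 2 max |x_p' y| in the working space
        expected = 2 * np.max(np.abs(path.X_work.T @ path.y_work))
        assert lam_max == pytest.approx(expected)
        assert (path.coef_at(lam_max) == 0).all()
        assert (path.coef_at(lam_max * 2) == 0).all()

    def test_orthonormal_design_soft_threshold(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        path = lars_lasso_path(Q, y, center=False, standardize=False)
        bols = Q.T @ y
        for lam in (0.05, 0.4, 1.0):
            np.testing.assert_allclose(
                path.coef_at(lam), helpers.soft_threshold(bols, lam / 2), atol=1e-10
            )

    def test_kkt_at_all_knots(self, rng):
        for _ in range(8):
            I, P = int(rng.integers(10, 30)), int(rng.integers(20, 80))
            X = rng.normal(size=(I, P))
            y = rng.normal(size=I) + X[:, 0]
            path = lars_lasso_path(X, y)
            assert path.max_kkt_violation() <= 1e-8

    def test_matches_coordinate_descent_oracle(self, rng):
        worst = 0.0
        for _ in range(10):
            I, P = int(rng.integers(10, 31)), int(rng.integers(10, 101))
            X = rng.normal(size=(I, P))
            y = rng.normal(size=I) + 2 * X[:, 0]
            path = lars_lasso_path(X, y)
            Xw, yw = path.X_work, path.y_work
            for lam in np.geomspace(path.lambdas[0] * 0.9,
                                    path.lambdas[0] * 1e-3, 8):
                b = path.coef_at(lam)
                obj = lasso_objective(Xw, yw, b, lam)
                oracle = Lasso(alpha=lam / (2 * I), fit_intercept=False,
                               tol=1e-12, max_iter=200_000).fit(Xw, yw)
                obj_cd = lasso_objective(Xw, yw, oracle.coef_, lam)
                worst = max(worst, (obj - obj_cd) / max(abs(obj_cd), 1e-12))
        assert worst <= 1e-6

    def test_active_set_never_exceeds_limit(self, rng):
        I, P = 12, 200
        X = rng.normal(size=(I, P))
        y = rng.normal(size=I)
        path = lars_lasso_path(X, y)
        assert max((c != 0).sum() for c in path.coefs) <= I - 1

    def test_duplicate_columns_lowest_index_enters(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, x, rng.normal(size=30)])
        y = 2 * x + rng.normal(size=30, scale=0.1)
        path = lars_lasso_path(X, y)
        first_active = path.active_sets[1]
        assert 0 in first_active and 1 not in first_active

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant response"):
            lars_lasso_path(rng.normal(size=(5, 3)), np.ones(5))


class TestCoefficientsAtLambda:
    @pytest.fixture
    def path(self, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20) + X[:, 3]
        return lars_lasso_path(X, y)

    def test_knot_values_returned_exactly(self, path):
        k = len(path.lambdas) // 2
        np.testing.assert_array_equal(
            coefficients_at_lambda(path, path.lambdas[k]), path.coefs[k]
        )

    def test_midpoint_satisfies_kkt(self, path):
        lam = 0.5 * (path.lambdas[2] + path.lambdas[3])
        b = coefficients_at_lambda(path, lam)
        g = 2 * path.X_work.T @ (path.y_work - path.X_work @ b)
        active = b != 0
        scale = max(path.lambdas[0], 1.0)
        assert np.max(np.abs(np.abs(g[active]) - lam)) / scale <= 1e-8
        assert (np.max(np.abs(g[~active])) - lam) / scale <= 1e-8

    def test_negative_lambda_rejected(self, path):
        with pytest.raises(ValueError):
            coefficients_at_lambda(path, -1.0)


class TestCrossValidation:
    def test_same_seed_identical_selection(self, rng):
        X = rng.normal(size=(30, 60))
        y = X[:, 5] - X[:, 17] + rng.normal(size=30, scale=0.5)
        a = cv_select_lambda(X, y, k=5, seed=3)
        b = cv_select_lambda(X, y, k=5, seed=3)
        assert a.lambda_star == b.lambda_star
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_array_equal(a.cv_mean, b.cv_mean)

    def test_fold_count_validation(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        with pytest.raises(ValueError, match="k must be"):
            cv_select_lambda(X, y, k=9)
        with pytest.raises(ValueError, match="k must be"):
            cv_select_lambda(X, y, k=1)

    def test_pure_noise_selects_few(self, rng):
        """With no real signal, min-CV lasso keeps the selected set small."""
        sizes = []
        for rep in range(10):
            X = rng.normal(size=(60, 400))
            y = rng.normal(size=60)
            res = cv_select_lambda(X, y, k=10, seed=rep)
            sizes.append(len(res.selected))
        assert np.median(sizes) <= 5


class TestLogisticLasso:
    def test_above_lambda_max_intercept_only(self, rng):
        X = rng.normal(size=(50, 20))
        X -= X.mean(0)
        y = (rng.random(50) < 0.4).astype(float)
        lam_max = logistic_lambda_max(X, y)
        b0s, betas = logistic_lasso(X, y, np.array([lam_max * 1.05]))
        assert (betas == 0).all()
        assert b0s[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_lambda_to_zero_matches_unpenalized_logistic(self, rng):
        I, P = 40, 10
        X = rng.normal(size=(I, P))
        X -= X.mean(0)
        beta = np.zeros(P)
        beta[:3] = [1.0, -1.0, 0.8]
        y = (rng.random(I) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
        lam_max = logistic_lambda_max(X, y)
        b0s, betas = logistic_lasso(
            X, y, np.geomspace(lam_max, lam_max * 1e-7, 90), tol=1e-10
        )
        fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="lbfgs",
                                                  maxiter=5000)
        np.testing.assert_allclose(betas[-1], fit.params[1:], atol=1e-4)
        assert b0s[-1] == pytest.approx(fit.params[0], abs=1e-4)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single-class"):
            logistic_lasso(X, np.ones(10), np.array([1.0]))

    def test_increasing_grid_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([0, 1] * 5, dtype=float)
        with pytest.raises(ValueError, match="decreasing"):
            logistic_lasso(X, y, np.array([1.0, 2.0]))


class TestSelectMarkers:
    def test_continuous_dispatches_to_lars(self, small_cohort):
        result, table = select_markers(small_cohort.cn, small_cohort.response,
                                       k=4, seed=0)
        assert result.response_kind == "continuous"
        assert result.path is not None
        assert set(table.columns) == {"marker_id", "chromosome", "position",
                                      "coefficient"}

    def test_binary_dispatches_to_logistic(self, small_cohort):
        y = (small_cohort.response.values > np.median(small_cohort.response.values))
        resp = ResponseVector(small_cohort.response.samples, y.astype(float),
                              "binary")
        result, _ = select_markers(small_cohort.cn, resp, k=4, seed=0)
        assert result.response_kind == "binary"
        assert result.path is None

    def test_sample_mismatch_is_error(self, small_cohort):
        resp = ResponseVector(["X1"], [1.0])
        with pytest.raises(ValueError, match="missing"):
            select_markers(small_cohort.cn, resp)

    def test_model_results_interface(self, small_cohort):
        res = MarkerSelectionModel(small_cohort.cn, small_cohort.response).fit(
            k=4, seed=1
        )
        assert "lambda*" in res.summary()
        curve = res.cv_curve()
        assert {"lambda", "cv_error", "cv_se"} <= set(curve.columns)
        assert (curve["cv_error"] >= 0).all()

    def test_smoothed_design_integration(self, small_cohort):
        from multicna.segmentation import SegmentationModel

        seg = SegmentationModel(small_cohort.cn).fit()
        res, table = select_markers(
            small_cohort.cn, small_cohort.response,
            smooth_segments=seg.segments, k=4, seed=0,
        )
        assert res.lambda_star > 0
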