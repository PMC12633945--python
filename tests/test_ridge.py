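"""Ridge estimator contracts against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agegap import (
    AlphaGrid,
    RidgePath,
    ScalerParams,
    RidgeModel,
    fit_ridge,
    mean_absolute_error,
    model_from_json,
    model_to_json,
    predict_age,
    select_alpha_cv,
)


def normal_equation_weights(Xs, yc, alpha):
    """Independent oracle: dense solve of (X'X + alpha I) w = X'y."""
    p = Xs.shape[1]
    return np.linalg.solve(Xs.T @ Xs + alpha * np.eye(p), Xs.T @ yc)


class TestFit:
    def test_ols_perfect_interpolation(self):
        X = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([1.0, 2.0, 3.0])
        model = fit_ridge(X, y, alpha=0.0)
        assert np.allclose(predict_age(model, X), y)

    def test_infinite_shrinkage_predicts_train_mean(self):
        X = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([1.0, 2.0, 3.0])
        model = fit_ridge(X, y, alpha=1e12)
        assert np.allclose(predict_age(model, X), 2.0, atol=1e-6)

    def test_weights_match_normal_equation_oracle(self, rng):
        X = rng.normal(size=(50, 20))
        y = rng.normal(size=50)
        model = fit_ridge(X, y, alpha=3.7)
        Xs = model.scaler.transform(X)
        expected = normal_equation_weights(Xs, y - y.mean(), 3.7)
        assert np.allclose(model.weights, expected, atol=1e-8)

    def test_refit_identical(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        a, b = fit_ridge(X, y, 1.0), fit_ridge(X, y, 1.0)
        assert np.array_equal(a.weights, b.weights) and a.intercept == b.intercept

    def test_zero_variance_feature_named(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 4.2
        with pytest.raises(ValueError, match="colB"):
            fit_ridge(X, rng.normal(size=20), 1.0, feature_names=["colA", "colB", "colC"])

    def test_alpha_zero_rank_deficient_instructs_positive_alpha(self, rng):
        X = rng.normal(size=(5, 10))
        with pytest.raises(ValueError, match="alpha > 0"):
            fit_ridge(X, rng.normal(size=5), 0.0)

    def test_monotone_shrinkage_in_alpha(self, rng):
        X = rng.normal(size=(60, 12))
        y = rng.normal(size=60)
        path = RidgePath(X, y)
        norms = [np.linalg.norm(path.weights(a)) for a in np.logspace(-4, 6, 25)]
        assert np.all(np.diff(norms) <= 1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 1000))
    def test_scaling_equivariance(self, scale, seed):
        # rescaling a raw feature column leaves predictions unchanged
        r = np.random.default_rng(seed)
        X = r.normal(size=(40, 4))
        y = r.normal(size=40)
        base = predict_age(fit_ridge(X, y, 2.0), X)
        X2 = X.copy()
        X2[:, 2] *= scale
        assert np.allclose(predict_age(fit_ridge(X2, y, 2.0), X2), base, atol=1e-8)


class TestPredict:
    def test_zero_weights_yield_intercept(self):
        model = RidgeModel(1.0, np.zeros(2), 63.0, ScalerParams(np.zeros(2), np.ones(2)))
        assert np.allclose(predict_age(model, np.random.default_rng(0).normal(size=(5, 2))), 63.0)

    def test_hand_evaluated_affine_map(self):
        model = RidgeModel(0.0, np.array([2.0]), 60.0, ScalerParams(np.array([1.0]), np.array([1.0])))
        assert predict_age(model, np.array([[3.0]]))[0] == pytest.approx(64.0)

    def test_ols_residuals_orthogonal_to_features(self, rng):
        X = rng.normal(size=(100, 6))
        y = rng.normal(size=100)
        model = fit_ridge(X, y, 0.0)
        resid = y - predict_age(model, X)
        assert np.allclose(model.scaler.transform(X).T @ resid, 0.0, atol=1e-8)

    def test_column_mismatch_raises(self, rng):
        model = fit_ridge(rng.normal(size=(10, 3)), rng.normal(size=10), 1.0)
        with pytest.raises(ValueError, match="feature count"):
            predict_age(model, rng.normal(size=(4, 2)))


class TestAlphaSelection:
    def test_noiseless_linear_picks_grid_minimum(self, rng):
        X = rng.normal(size=(50, 1))
        y = 3.0 * X[:, 0] + 5.0
        grid = AlphaGrid(np.logspace(-5, 3, 9))
        best, errs = select_alpha_cv(X, y, grid)
        assert best == grid.values[0]
        assert errs[0] < 1e-10

    def test_single_value_grid_returned(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        best, errs = select_alpha_cv(X, y, AlphaGrid([2.5]))
        assert best == 2.5 and errs.shape == (1,)

    def test_loo_fast_path_matches_naive_refit(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40) * 5 + 60
        grid = AlphaGrid(np.logspace(-2, 3, 6))
        _, fast = select_alpha_cv(X, y, grid)
        # naive oracle: same fixed full-sample scaler, refit dropping each row
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        naive = []
        for alpha in grid.values:
            errs = []
            for i in range(len(y)):
                mask = np.arange(len(y)) != i
                A = np.c_[np.ones(mask.sum()), Xs[mask]]
                D = np.diag([0.0] + [alpha] * X.shape[1])
                beta = np.linalg.solve(A.T @ A + D, A.T @ y[mask])
                pred = beta[0] + Xs[i] @ beta[1:]
                errs.append((y[i] - pred) ** 2)
            naive.append(np.mean(errs))
        assert np.allclose(fast, naive, rtol=1e-6)

    def test_kfold_matches_bruteforce_refit(self, rng):
        # simulated n=200, p=50, noise sd 5
        X = rng.normal(size=(200, 50))
        beta = rng.normal(size=50)
        y = X @ beta + rng.normal(scale=5.0, size=200)
        grid = AlphaGrid(np.logspace(-3, 4, 8))
        _, errs = select_alpha_cv(X, y, grid, n_folds=5, seed=123)
        # brute-force oracle replaying the same fold layout
        order = np.random.default_rng(123).permutation(200)
        folds = np.array_split(order, 5)
        sse = np.zeros(len(grid.values))
        for held in folds:
            mask = np.ones(200, dtype=bool)
            mask[held] = False
            mu, sd = X[mask].mean(0), X[mask].std(0)
            Xs, yc = (X[mask] - mu) / sd, y[mask] - y[mask].mean()
            for a, alpha in enumerate(grid.values):
                w = normal_equation_weights(Xs, yc, alpha)
                pred = y[mask].mean() + ((X[held] - mu) / sd) @ w
                sse[a] += ((y[held] - pred) ** 2).sum()
        assert np.allclose(errs, sse / 200, rtol=1e-6)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            AlphaGrid([])


class TestMAE:
    def test_identical_vectors_zero(self):
        assert mean_absolute_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert mean_absolute_error([60.0, 70.0], [62.0, 66.0]) == pytest.approx(3.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mean_absolute_error([1.0], [1.0, 2.0])

    def test_constant_predictor_on_uniform_ages(self, rng):
        # mean absolute deviation of U(45, 80) about its mean is range/4
        ages = rng.uniform(45, 80, size=200_000)
        assert mean_absolute_error(ages, np.full_like(ages, ages.mean())) == pytest.approx(
            8.75, abs=0.05
        )


class TestSerialization:
    def test_json_round_trip_lossless(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30) * 7 + 55
        model = fit_ridge(X, y, 0.37, feature_names=list("abcd"))
        back = model_from_json(model_to_json(model))
        assert np.array_equal(back.weights, model.weights)
        assert back.intercept == model.intercept
        assert np.array_equal(back.scaler.mean, model.scaler.mean)
        assert np.array_equal(back.scaler.sd, model.scaler.sd)
        assert back.feature_names == model.feature_names
        assert np.array_equal(predict_age(back, X), predict_age(model, X))
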