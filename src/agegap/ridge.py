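"""Standard-scaled ridge regression for brain-age prediction.

The estimator is the classical penalized least-squares closed form on
standardized features: with X the column-standardized training matrix and
y centred at its mean, the weights solve ``(X'X + alpha I) w = X'(y - ybar)``
and the intercept is ``ybar``.  Internally the solve goes through one SVD of
the scaled design, which is numerically stable and makes whole-alpha-grid
fits (the regularization sweeps) essentially free after the decomposition.

Cross-validated alpha selection follows the RidgeCV convention: exact
leave-one-out error via the hat-diagonal identity by default, with a k-fold
option that refits the scaler inside each fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AlphaGrid",
    "RidgePath",
    "RidgeModel",
    "ScalerParams",
    "fit_ridge",
    "mean_absolute_error",
    "model_from_json",
    "model_to_json",
    "predict_age",
    "select_alpha_cv",
]


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature standardization parameters fit on training data only."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


@dataclass(frozen=True)
class RidgeModel:
    """A fitted ridge age model: ``pred = intercept + scaled(x) . weights``."""

    alpha: float
    weights: np.ndarray
    intercept: float
    scaler: ScalerParams
    feature_names: tuple[str, ...] | None = None

    @property
    def train_target_mean(self) -> float:
        """Mean training age; identical to the intercept by construction."""
        return self.intercept


@dataclass(frozen=True)
class AlphaGrid:
    """Strictly increasing grid of L2 strengths.

    The default replicates the reference 100-tick log-spaced grid from
    1e-5 to 1e5.
    """

    values: np.ndarray = field(
        default_factory=lambda: np.logspace(-5.0, 5.0, 100)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValueError("alpha grid is empty")
        if np.any(self.values <= 0):
            raise ValueError("alpha grid values must be positive")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("alpha grid must be strictly increasing")


def _validate_design(X: np.ndarray, feature_names: Sequence[str] | None) -> None:
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing or non-finite values")


def _fit_scaler(X: np.ndarray, feature_names: Sequence[str] | None) -> ScalerParams:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    # constant columns have sd ~ eps*|mean|, not exactly 0
    degenerate = sd <= 1e-10 * np.maximum(1.0, np.abs(mean))
    if np.any(degenerate):
        bad = int(np.flatnonzero(degenerate)[0])
        name = feature_names[bad] if feature_names is not None else f"column {bad}"
        raise ValueError(f"zero-variance feature: {name}")
    return ScalerParams(mean=mean, sd=sd)


class RidgePath:
    """One SVD of a scaled, centred training design; weights for any alpha.

    Used by :func:`fit_ridge` for single fits and by the sweep machinery to
    evaluate a whole alpha grid from a single decomposition.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        _validate_design(X, feature_names)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        if X.shape[0] != y.shape[0]:
            raise ValueError("feature matrix and age vector have different lengths")
        if not np.all(np.isfinite(y)):
            raise ValueError("age vector contains missing or non-finite values")
        self.feature_names = tuple(feature_names) if feature_names is not None else None
        self.scaler = _fit_scaler(X, feature_names)
        self.n, self.p = X.shape
        self.intercept = float(y.mean())
        Xs = self.scaler.transform(X)
        yc = y - self.intercept
        # Economy SVD: Xs = U diag(s) Vt
        self.U, self.s, self.Vt = np.linalg.svd(Xs, full_matrices=False)
        self.Uty = self.U.T @ yc
        self._Xs = Xs
        self._yc = yc

    def weights(self, alpha: float) -> np.ndarray:
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        if alpha == 0:
            tol = self.s[0] * max(self.n, self.p) * np.finfo(float).eps if self.s.size else 0.0
            if self.p > self.n or np.any(self.s <= tol):
                raise ValueError(
                    "singular system at alpha=0 (rank-deficient design); use alpha > 0"
                )
            shrink = 1.0 / self.s
        else:
            shrink = self.s / (self.s**2 + alpha)
        return self.Vt.T @ (shrink * self.Uty)

    def model(self, alpha: float) -> RidgeModel:
        return RidgeModel(
            alpha=float(alpha),
            weights=self.weights(alpha),
            intercept=self.intercept,
            scaler=self.scaler,
            feature_names=self.feature_names,
        )

    def weight_matrix(self, alphas: np.ndarray) -> np.ndarray:
        """Weights for every alpha in one shot; shape (n_alpha, p)."""
        alphas = np.asarray(alphas, dtype=float)
        shrink = self.s[None, :] / (self.s[None, :] ** 2 + alphas[:, None])
        return (shrink * self.Uty[None, :]) @ self.Vt

    def loo_mse(self, alphas: np.ndarray) -> np.ndarray:
        """Exact leave-one-out mean squared error per alpha.

        Uses the identity e_i = r_i / (1 - h_ii) for penalized least squares
        with an unpenalized intercept; because the scaled columns are centred
        the hat matrix decomposes as J/n + U diag(d) U'.
        """
        alphas = np.asarray(alphas, dtype=float)
        d = self.s[None, :] ** 2 / (self.s[None, :] ** 2 + alphas[:, None])  # (A, r)
        fitted = (d * self.Uty[None, :]) @ self.U.T  # (A, n)
        resid = self._yc[None, :] - fitted
        h = 1.0 / self.n + d @ (self.U.T**2)  # (A, n)
        loo = resid / (1.0 - h)
        return (loo**2).mean(axis=1)


def fit_ridge(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    feature_names: Sequence[str] | None = None,
) -> RidgeModel:
    """Fit a standard-scaled ridge model of age on features.

    The scaler is fit on the supplied training data only.  Refitting on
    identical input reproduces an identical model.
    """
    return RidgePath(X, y, feature_names).model(alpha)


def predict_age(model: RidgeModel, X: np.ndarray) -> np.ndarray:
    """Predicted ages: ``intercept + scaled(X) . weights``.  Pure function."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1] if X.ndim == 2 else 'n/a'} does not match "
            f"model ({model.weights.shape[0]} features)"
        )
    return model.intercept + model.scaler.transform(X) @ model.weights


def select_alpha_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: AlphaGrid | None = None,
    n_folds: int | None = None,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Pick alpha by cross-validation over the grid.

    ``n_folds=None`` (default) uses exact leave-one-out on data scaled once
    on the full training sample; an integer uses shuffled k-fold with the
    scaler refit inside every fold.  Returns ``(best_alpha, cv_mse_per_alpha)``;
    ties in CV error break toward larger alpha (more shrinkage).
    """
    if grid is None:
        grid = AlphaGrid()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_folds is None:
        errors = RidgePath(X, y).loo_mse(grid.values)
    else:
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if X.shape[0] < n_folds:
            raise ValueError("need at least n_folds rows")
        rng = np.random.default_rng(seed)
        order = rng.permutation(X.shape[0])
        folds = np.array_split(order, n_folds)
        sse = np.zeros(grid.values.size)
        for held in folds:
            mask = np.ones(X.shape[0], dtype=bool)
            mask[held] = False
            path = RidgePath(X[mask], y[mask])
            W = path.weight_matrix(grid.values)  # (A, p)
            preds = path.intercept + path.scaler.transform(X[held]) @ W.T  # (n_h, A)
            sse += ((y[held][:, None] - preds) ** 2).sum(axis=0)
        errors = sse / X.shape[0]
    best_idx = errors.size - 1 - int(np.argmin(errors[::-1]))  # tie -> larger alpha
    return float(grid.values[best_idx]), errors


def mean_absolute_error(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error in years, the primary accuracy metric."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean(np.abs(y - yhat)))


def model_to_json(model: RidgeModel, path: str | Path | None = None) -> str:
    """Serialize a model losslessly (float hex preserves every bit)."""
    payload = {
        "alpha": model.alpha,
        "weights": [w.hex() for w in model.weights.tolist()],
        "intercept": model.intercept.hex(),
        "scaler_mean": [m.hex() for m in model.scaler.mean.tolist()],
        "scaler_sd": [s.hex() for s in model.scaler.sd.tolist()],
        "feature_names": list(model.feature_names) if model.feature_names else None,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> RidgeModel:
    """Inverse of :func:`model_to_json`; accepts a path or a JSON string."""
    text = Path(source).read_text() if isinstance(source, Path) else source
    if isinstance(source, str) and not source.lstrip().startswith("{"):
        text = Path(source).read_text()
    payload = json.loads(text)
    return RidgeModel(
        alpha=float(payload["alpha"]),
        weights=np.array([float.fromhex(w) for w in payload["weights"]]),
        intercept=float.fromhex(payload["intercept"]),
        scaler=ScalerParams(
            mean=np.array([float.fromhex(m) for m in payload["scaler_mean"]]),
            sd=np.array([float.fromhex(s) for s in payload["scaler_sd"]]),
        ),
        feature_names=tuple(payload["feature_names"]) if payload["feature_names"] else None,
    )
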