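"""Exact additive feature attributions for linear age models.

For a linear model under the independent-feature convention the Shapley
value of feature j for subject i is closed-form:

    phi_ij = w_j * (z_ij - mean_background z_j)

on the standardized feature scale (equivalently ``(w_j / sd_j) * (x_ij -
mean background x_j)`` in raw units), and the per-subject attributions sum
exactly to ``prediction_i - mean background prediction`` (local accuracy).
Attributions are in years.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .ridge import RidgeModel

__all__ = [
    "attribution_shift",
    "attribution_table_from_models",
    "linear_shap",
    "mean_abs_attribution",
    "rank_features",
]


def linear_shap(model: RidgeModel, samples: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Per-sample per-feature attributions relative to a background sample.

    Returns an (n_samples, n_features) array whose rows sum to
    ``predict(sample) - mean(predict(background))`` exactly.
    """
    samples = np.asarray(samples, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a nonempty 2-D matrix")
    p = model.weights.shape[0]
    if samples.ndim != 2 or samples.shape[1] != p or background.shape[1] != p:
        raise ValueError("column count does not match the model")
    w_raw = model.weights / model.scaler.sd  # weights on the raw feature scale
    return (samples - background.mean(axis=0)) * w_raw


def mean_abs_attribution(
    model: RidgeModel, samples: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Per-feature mean |attribution| over samples (the importance summary)."""
    return np.abs(linear_shap(model, samples, background)).mean(axis=0)


def attribution_table_from_models(
    alphas: np.ndarray,
    models: Sequence,
    samples: np.ndarray,
    feature_names: Sequence[str],
) -> pd.DataFrame:
    """Mean |attribution| per (alpha, feature), averaged over resamples.

    ``models`` are per-resample model families exposing ``weights_raw``
    (n_alpha x n_features, raw-scale weights) and ``background_mean`` (the
    training resample mean, the attribution reference point).  For a linear
    model ``|phi_ij| = |w_j| * |x_ij - bg_j|`` factorises, so the per-alpha
    importance is ``|w_j(alpha)| * mean_i |x_ij - bg_j|``.
    """
    if not models:
        raise ValueError("no models supplied")
    samples = np.asarray(samples, dtype=float)
    acc = np.zeros((len(alphas), len(feature_names)))
    for m in models:
        spread = np.abs(samples - m.background_mean[None, :]).mean(axis=0)  # (p,)
        acc += np.abs(m.weights_raw) * spread[None, :]
    return pd.DataFrame(acc / len(models), index=pd.Index(alphas, name="alpha"), columns=list(feature_names))


def rank_features(
    mean_abs: pd.DataFrame | pd.Series, k: int = 10
) -> pd.DataFrame:
    """Top-k features by mean |attribution|, per alpha.

    ``mean_abs`` is a Series (one model) or a DataFrame indexed by alpha with
    one column per feature, already averaged over resamples.  Ties break
    deterministically by feature name.  Values are reported both raw and
    relative to the per-alpha maximum.
    """
    if isinstance(mean_abs, pd.Series):
        mean_abs = mean_abs.to_frame().T
    if k > mean_abs.shape[1]:
        raise ValueError("k exceeds the feature count")
    rows = []
    for alpha, row in mean_abs.iterrows():
        ordered = row.sort_index().sort_values(ascending=False, kind="stable")
        top = ordered.iloc[:k]
        peak = float(top.iloc[0]) if len(top) else 0.0
        for rank, (feat, val) in enumerate(top.items(), start=1):
            rows.append(
                {
                    "alpha": alpha,
                    "rank": rank,
                    "feature": feat,
                    "mean_abs_shap": float(val),
                    "relative": float(val) / peak if peak > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def attribution_shift(
    mean_abs: pd.DataFrame | pd.Series, global_features: Sequence[str]
) -> pd.Series:
    """Fraction of total mean |attribution| carried by the designated
    global/disease-sensitive feature set, per alpha.

    Returns NaN (with a warning) where the total attribution mass is zero.
    """
    if len(global_features) == 0:
        raise ValueError("the designated global feature set is empty")
    if isinstance(mean_abs, pd.Series):
        mean_abs = mean_abs.to_frame().T
    unknown = set(global_features) - set(mean_abs.columns)
    if unknown:
        raise ValueError(f"unknown feature ids: {sorted(unknown)}")
    total = mean_abs.sum(axis=1)
    part = mean_abs[list(global_features)].sum(axis=1)
    if (total == 0).any():
        warnings.warn("zero total attribution mass; global_mass undefined there", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mass = part / total
    mass[total == 0] = np.nan
    mass.name = "global_mass"
    return mass
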