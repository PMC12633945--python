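"""Sample-level linear bias correction of brain-age gaps.

Shrinkage age predictors regress toward the training mean, so the raw gap
(predicted minus chronological age) carries a spurious negative trend in
age.  The standard sample-level fix is an OLS of raw gap on age across the
test sample, analysing the residuals thereafter; by default the fit pools
patients and healthy test subjects (a healthy-only fit is available for
sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BiasCorrection", "GapTable", "apply_bias_correction", "fit_bias_correction", "make_gap_table"]

#: Column schema of a gap table (a plain DataFrame).
GapTable = pd.DataFrame


@dataclass(frozen=True)
class BiasCorrection:
    """OLS fit of raw gap on age: ``expected_gap(age) = intercept + slope * age``."""

    slope: float
    intercept: float
    n_fit: int


def make_gap_table(
    subject_id: pd.Index | np.ndarray,
    age: np.ndarray,
    predicted_age: np.ndarray,
    group: np.ndarray | list[str],
) -> GapTable:
    """Assemble a gap table; ``raw_gap = predicted_age - age`` exactly."""
    age = np.asarray(age, dtype=float)
    predicted_age = np.asarray(predicted_age, dtype=float)
    return pd.DataFrame(
        {
            "subject_id": np.asarray(subject_id),
            "age": age,
            "predicted_age": predicted_age,
            "raw_gap": predicted_age - age,
            "group": np.asarray(group, dtype=object),
        }
    )


def fit_bias_correction(gaps: GapTable, healthy_only: bool = False) -> BiasCorrection:
    """OLS of raw gap on age over the supplied test rows.

    By default every row (patients and controls together) enters the fit;
    ``healthy_only=True`` restricts to rows whose group is ``"healthy-test"``.
    """
    frame = gaps
    if healthy_only:
        frame = gaps[gaps["group"] == "healthy-test"]
    if len(frame) < 3:
        raise ValueError(f"need at least 3 rows to fit the correction, got {len(frame)}")
    age = frame["age"].to_numpy(dtype=float)
    gap = frame["raw_gap"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant; bias correction is not identified")
    slope, intercept = np.polyfit(age, gap, 1)
    return BiasCorrection(slope=float(slope), intercept=float(intercept), n_fit=len(frame))


def apply_bias_correction(gaps: GapTable, corr: BiasCorrection) -> GapTable:
    """Attach ``corrected_gap = raw_gap - (slope * age + intercept)``.

    On the fitting sample the residuals have zero mean and zero Pearson
    correlation with age to numerical precision (OLS orthogonality).
    """
    out = gaps.copy()
    out["corrected_gap"] = out["raw_gap"] - (corr.slope * out["age"] + corr.intercept)
    return out
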