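"""Effect sizes for patient-vs-matched-control comparisons of corrected gaps.

Cohen's d with the pooled-SD denominator (the default definition; a Hedges
small-sample correction is available via flag) and a within-group bootstrap
standard error.  Sign convention: positive d means patients look older than
their matched controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["EffectSizeResult", "bootstrap_se", "cohens_d"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectSizeResult:
    condition: str
    d: float
    se: float
    n_pairs: int
    sign_convention: str = "positive = patients older-appearing"


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = x.size, y.size
    return float(
        np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    )


def cohens_d(
    gaps_patients: np.ndarray, gaps_controls: np.ndarray, hedges: bool = False
) -> float:
    """Pooled-SD Cohen's d of patients minus controls.

    ``hedges=True`` applies the small-sample correction factor
    ``1 - 3 / (4 (n1 + n2) - 9)``.
    """
    x = np.asarray(gaps_patients, dtype=float)
    y = np.asarray(gaps_controls, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    sd = _pooled_sd(x, y)
    if sd == 0:
        raise ValueError("zero pooled SD; effect size undefined")
    d = (x.mean() - y.mean()) / sd
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (x.size + y.size) - 9.0)
    return float(d)


def bootstrap_se(
    gaps_patients: np.ndarray,
    gaps_controls: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap SE of Cohen's d, resampling with replacement within groups.

    Degenerate resamples (zero pooled SD) are redrawn and their count logged.
    Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    x = np.asarray(gaps_patients, dtype=float)
    y = np.asarray(gaps_controls, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    rng = np.random.default_rng(seed)

    def batch(k: int) -> np.ndarray:
        bx = x[rng.integers(0, x.size, size=(k, x.size))]
        by = y[rng.integers(0, y.size, size=(k, y.size))]
        n1, n2 = x.size, y.size
        v = ((n1 - 1) * bx.var(axis=1, ddof=1) + (n2 - 1) * by.var(axis=1, ddof=1)) / (
            n1 + n2 - 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (bx.mean(axis=1) - by.mean(axis=1)) / np.sqrt(v)
        return d[v > 0]

    draws = batch(n_boot)
    redrawn = 0
    while draws.size < n_boot:
        redrawn += n_boot - draws.size
        draws = np.concatenate([draws, batch(n_boot - draws.size)])
    if redrawn:
        log.info("redrew %d degenerate bootstrap resamples", redrawn)
    return float(draws[:n_boot].std(ddof=1))
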