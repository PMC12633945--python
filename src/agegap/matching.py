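"""Propensity-score matching of patients to healthy controls.

Logistic propensity model on the matching covariates, greedy 1:1
nearest-neighbour matching without replacement on the logit score, and a
caliper expressed in units of the pooled logit-score SD (the
Rosenbaum-Rubin convention; 0.25 SD by default).  Balance is reported as
standardized mean differences before and after matching.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "MatchedCohort",
    "PropensityModel",
    "balance_diagnostics",
    "fit_propensity",
    "match_caliper",
    "propensity_scores",
]


@dataclass(frozen=True)
class PropensityModel:
    """Fitted logistic model of case status on the matching covariates."""

    coefficients: pd.Series  # per covariate
    intercept: float
    converged: bool
    score_scale: str = "logit"


@dataclass
class MatchedCohort:
    """1:1 matched pairs with caliper bookkeeping and balance diagnostics."""

    pairs: pd.DataFrame  # patient_id, control_id, distance (|logit difference|)
    caliper_width: float
    unmatched_patients: list
    balance: pd.DataFrame | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def fit_propensity(covariates: pd.DataFrame, is_patient: np.ndarray) -> PropensityModel:
    """Maximum-likelihood logistic regression of case status on covariates."""
    y = np.asarray(is_patient, dtype=float)
    if covariates.isna().any().any():
        raise ValueError("covariates contain missing values")
    if y.min() == y.max():
        raise ValueError("both patients and controls must be present")
    design = sm.add_constant(covariates.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(
            "perfect separation in the propensity model; consider exact matching "
            "without a caliper or a penalized fit"
        ) from exc
    params = pd.Series(res.params, index=design.columns)
    return PropensityModel(
        coefficients=params.drop("const"),
        intercept=float(params["const"]),
        converged=bool(res.mle_retvals.get("converged", False)),
    )


def propensity_scores(model: PropensityModel, covariates: pd.DataFrame) -> np.ndarray:
    """Logit-scale propensity scores for the given covariate table."""
    cols = list(model.coefficients.index)
    return (
        model.intercept + covariates[cols].to_numpy(dtype=float) @ model.coefficients.to_numpy()
    )


def match_caliper(
    scores: np.ndarray,
    is_patient: np.ndarray,
    ids: np.ndarray | pd.Index,
    caliper_sd: float = 0.25,
    seed: int | None = None,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    The caliper width is ``caliper_sd`` times the SD of the logit scores over
    the pooled sample.  Patient order is randomized by ``seed`` for
    reproducible tie-breaking; each control is used at most once; patients
    with no available control within the caliper are reported unmatched.
    """
    if caliper_sd <= 0:
        raise ValueError("caliper_sd must be > 0")
    scores = np.asarray(scores, dtype=float)
    is_patient = np.asarray(is_patient, dtype=bool)
    ids = np.asarray(ids)
    if not np.any(~is_patient):
        raise ValueError("no controls available for matching")
    caliper_width = float(caliper_sd * scores.std())

    rng = np.random.default_rng(seed)
    patient_pos = np.flatnonzero(is_patient)
    patient_pos = patient_pos[rng.permutation(patient_pos.size)]
    control_pos = np.flatnonzero(~is_patient)
    order = np.argsort(scores[control_pos], kind="stable")
    ctrl_scores = list(scores[control_pos][order])
    ctrl_ids = list(ids[control_pos][order])

    rows, unmatched = [], []
    for pos in patient_pos:
        s = scores[pos]
        if not ctrl_scores:
            unmatched.append(ids[pos])
            continue
        j = bisect.bisect_left(ctrl_scores, s)
        # nearest of the two neighbours in the sorted available controls
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(ctrl_scores):
                dist = abs(ctrl_scores[cand] - s)
                if best is None or dist < best[1]:
                    best = (cand, dist)
        if best is None or best[1] > caliper_width:
            unmatched.append(ids[pos])
            continue
        cand, dist = best
        rows.append((ids[pos], ctrl_ids[cand], dist))
        del ctrl_scores[cand], ctrl_ids[cand]

    pairs = pd.DataFrame(rows, columns=["patient_id", "control_id", "distance"])
    assert pairs["control_id"].is_unique or pairs.empty
    assert pairs.empty or float(pairs["distance"].max()) <= caliper_width + 1e-12
    return MatchedCohort(pairs=pairs, caliper_width=caliper_width, unmatched_patients=unmatched)


def _smd(
    cov: pd.DataFrame, patient_ids: np.ndarray, control_ids: np.ndarray, denom: pd.Series
) -> pd.Series:
    mp = cov.loc[patient_ids].mean()
    mc = cov.loc[control_ids].mean()
    return (mp - mc) / denom


def balance_diagnostics(
    covariates: pd.DataFrame,
    is_patient: np.ndarray,
    matched: MatchedCohort,
) -> pd.DataFrame:
    """Standardized mean differences per covariate, pre- and post-match.

    SMD = (mean_patients - mean_controls) / pooled SD, with the pooled SD
    taken from the full pre-match groups for both stages so the two numbers
    are on one scale.  Zero pooled SD yields an SMD of 0 with a warning.
    """
    if matched.n_pairs < 1:
        raise ValueError("need at least one matched pair")
    is_patient = np.asarray(is_patient, dtype=bool)
    cov = covariates.astype(float)
    gp, gc = cov[is_patient], cov[~is_patient]
    n1, n2 = len(gp), len(gc)
    pooled = np.sqrt(
        ((n1 - 1) * gp.var(ddof=1) + (n2 - 1) * gc.var(ddof=1)) / (n1 + n2 - 2)
    )
    zero = pooled == 0
    if zero.any():
        warnings.warn(
            f"zero pooled SD for covariates {list(pooled.index[zero])}; SMD reported as 0",
            stacklevel=2,
        )
        pooled[zero] = np.inf
    before = _smd(cov, gp.index.to_numpy(), gc.index.to_numpy(), pooled)
    after = _smd(
        cov,
        matched.pairs["patient_id"].to_numpy(),
        matched.pairs["control_id"].to_numpy(),
        pooled,
    )
    return pd.DataFrame({"smd_before": before, "smd_after": after})
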