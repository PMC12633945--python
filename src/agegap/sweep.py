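"""Regularization and train-size sweeps over the full brain-age pipeline.

`run_alpha_sweep` orchestrates the over-regularization experiment: resample
healthy training sets, fit the ridge model at every alpha on the grid,
bias-correct gaps on the full test pool, score accuracy (MAE on healthy
test subjects only) and per-condition matched Cohen's d, and aggregate over
resamples.  `identify_regions` then locates the accuracy-optimal,
transition and detection-optimal regimes.  Matched cohorts are built once
per cohort and reused across every alpha and resample, so the model is the
only moving part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .bias import apply_bias_correction, fit_bias_correction, make_gap_table
from .effects import cohens_d
from .matching import MatchedCohort, PropensityModel, balance_diagnostics, fit_propensity, match_caliper, propensity_scores
from .ridge import AlphaGrid, RidgePath, select_alpha_cv
from .synthetic import SyntheticCohort, split_cohort

__all__ = [
    "ConditionRegions",
    "RegionReport",
    "StudyArms",
    "SweepResult",
    "TrainSizeResult",
    "identify_regions",
    "prepare_study",
    "run_alpha_sweep",
    "run_trainsize_sweep",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage integer seeds derived from a master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 1)) for s in state]


@dataclass
class StudyArms:
    """Frozen study design: pools plus one matched cohort per condition."""

    train_pool: SyntheticCohort
    test_pool: SyntheticCohort
    matched: dict[str, MatchedCohort]
    propensity: dict[str, PropensityModel]


def prepare_study(
    cohort: SyntheticCohort,
    test_fraction: float = 0.25,
    caliper_sd: float = 0.25,
    seed: int = 0,
) -> StudyArms:
    """Split the cohort and build one propensity-matched cohort per condition.

    Controls are drawn from healthy test-pool subjects (no diagnosed
    condition, never used for training); matching covariates are age plus
    the cohort's covariate columns.
    """
    split_seed, match_seed = _child_seeds(seed, 2)
    train_pool, test_pool = split_cohort(cohort, test_fraction, split_seed)

    cov_cols = ["age"] + list(cohort.covariate_names)
    healthy_test = ~test_pool.is_diagnosed.to_numpy()
    matched: dict[str, MatchedCohort] = {}
    prop: dict[str, PropensityModel] = {}
    match_seeds = _child_seeds(match_seed, len(cohort.condition_names))
    for cond, cseed in zip(cohort.condition_names, match_seeds):
        is_case = test_pool.subjects[cond].to_numpy(dtype=bool)
        pool_mask = is_case | healthy_test
        sub = test_pool.subjects.loc[pool_mask, cov_cols]
        y = is_case[pool_mask]
        model = fit_propensity(sub, y)
        scores = propensity_scores(model, sub)
        mc = match_caliper(scores, y, sub.index.to_numpy(), caliper_sd=caliper_sd, seed=cseed)
        mc.balance = balance_diagnostics(sub, y, mc)
        matched[cond] = mc
        prop[cond] = model
    return StudyArms(train_pool=train_pool, test_pool=test_pool, matched=matched, propensity=prop)


@dataclass
class ResampleModels:
    """Per-resample model family across the alpha grid (for attribution reuse)."""

    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    intercept: float
    weights: np.ndarray  # (n_alpha, p) on the scaled feature space
    background_mean: np.ndarray  # raw-scale mean of the training resample

    @property
    def weights_raw(self) -> np.ndarray:
        return self.weights / self.scaler_sd[None, :]


@dataclass
class SweepResult:
    """Everything the alpha sweep measured, cell-level and aggregated."""

    grid: np.ndarray
    mae: pd.DataFrame  # alpha, resample, mae
    d: pd.DataFrame  # alpha, condition, resample, d
    mae_agg: pd.DataFrame  # alpha, mean_mae, se_mae
    d_agg: pd.DataFrame  # alpha, condition, mean_d, se_d
    study: StudyArms
    models: list[ResampleModels] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)


def _aggregate(cells: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    g = cells.groupby(by, sort=True)[value]
    agg = g.agg(["mean", "sem"]).reset_index()
    return agg.rename(columns={"mean": f"mean_{value}", "sem": f"se_{value}"})


def run_alpha_sweep(
    cohort: SyntheticCohort,
    grid: AlphaGrid | None = None,
    n_train: int = 5000,
    n_resamples: int = 10,
    seed: int = 0,
    test_fraction: float = 0.25,
    caliper_sd: float = 0.25,
    study: StudyArms | None = None,
    healthy_only_correction: bool = False,
    keep_models: bool = True,
) -> SweepResult:
    """Run the full alpha sweep; deterministic given the master ``seed``.

    Per resample: draw ``n_train`` healthy training subjects, fit the ridge
    path, predict the whole test pool, fit and apply the linear bias
    correction on all test rows, then record MAE over healthy test subjects
    and matched Cohen's d per condition at every alpha.
    """
    if grid is None:
        grid = AlphaGrid()
    alphas = grid.values
    study_seed, resample_master = _child_seeds(seed, 2)
    if study is None:
        study = prepare_study(cohort, test_fraction, caliper_sd, seed=study_seed)
    train_pool, test_pool = study.train_pool, study.test_pool
    if len(train_pool.subjects) < n_train:
        raise ValueError(
            f"healthy training pool has {len(train_pool.subjects)} subjects, "
            f"fewer than the requested n_train={n_train}"
        )

    Xtr_all = train_pool.features.to_numpy()
    ytr_all = train_pool.subjects["age"].to_numpy(dtype=float)
    Xte = test_pool.features.to_numpy()
    age_te = test_pool.subjects["age"].to_numpy(dtype=float)
    healthy_te = ~test_pool.is_diagnosed.to_numpy()
    test_index = test_pool.subjects.index

    # Positional lookups for matched ids, fixed across alphas and resamples.
    pos = pd.Series(np.arange(len(test_index)), index=test_index)
    pair_pos = {
        cond: (
            pos[mc.pairs["patient_id"]].to_numpy(),
            pos[mc.pairs["control_id"]].to_numpy(),
        )
        for cond, mc in study.matched.items()
        if mc.n_pairs >= 2
    }

    fit_mask = healthy_te if healthy_only_correction else np.ones_like(healthy_te)
    fit_mask = fit_mask.astype(bool)
    age_fit = age_te[fit_mask]
    age_fit_c = age_fit - age_fit.mean()
    var_age_fit = float(age_fit_c @ age_fit_c)

    mae_rows, d_rows = [], []
    models: list[ResampleModels] = []
    for r, rseed in enumerate(_child_seeds(resample_master, n_resamples)):
        rng = np.random.default_rng(rseed)
        take = rng.choice(Xtr_all.shape[0], size=n_train, replace=False)
        path = RidgePath(Xtr_all[take], ytr_all[take], feature_names=cohort.feature_names)
        W = path.weight_matrix(alphas)  # (A, p)
        preds = path.intercept + path.scaler.transform(Xte) @ W.T  # (n_test, A)
        raw_gap = preds - age_te[:, None]

        # Vectorized OLS of raw gap on age over the correction sample, per alpha.
        gap_fit = raw_gap[fit_mask]
        slope = age_fit_c @ (gap_fit - gap_fit.mean(axis=0)) / var_age_fit  # (A,)
        intercept = gap_fit.mean(axis=0) - slope * age_fit.mean()
        corrected = raw_gap - (age_te[:, None] * slope[None, :] + intercept[None, :])

        mae = np.mean(np.abs(preds[healthy_te] - age_te[healthy_te, None]), axis=0)
        for a, alpha in enumerate(alphas):
            mae_rows.append((float(alpha), r, float(mae[a])))
            for cond, (pp, cp) in pair_pos.items():
                d_rows.append(
                    (float(alpha), cond, r, cohens_d(corrected[pp, a], corrected[cp, a]))
                )
        if keep_models:
            models.append(
                ResampleModels(
                    scaler_mean=path.scaler.mean,
                    scaler_sd=path.scaler.sd,
                    intercept=path.intercept,
                    weights=W,
                    background_mean=Xtr_all[take].mean(axis=0),
                )
            )

    mae_cells = pd.DataFrame(mae_rows, columns=["alpha", "resample", "mae"])
    d_cells = pd.DataFrame(d_rows, columns=["alpha", "condition", "resample", "d"])
    return SweepResult(
        grid=alphas,
        mae=mae_cells,
        d=d_cells,
        mae_agg=_aggregate(mae_cells, "mae", ["alpha"]),
        d_agg=_aggregate(d_cells, "d", ["alpha", "condition"]),
        study=study,
        models=models,
        conditions=sorted(pair_pos),
    )


@dataclass
class ConditionRegions:
    """Per-condition regime summary from a sweep."""

    alpha_d_opt: float
    d_at_d_opt: float
    d_at_mae_opt: float
    mae_at_d_opt: float
    sensitivity_gain: float
    transition: tuple[float, float]
    inverse_flag: bool


@dataclass
class RegionReport:
    alpha_mae_opt: float
    mae_at_opt: float
    per_condition: dict[str, ConditionRegions]
    alpha_majority_opt: float


def identify_regions(sweep: SweepResult) -> RegionReport:
    """Locate the accuracy-optimal, detection-optimal and transition regimes.

    ``alpha_mae_opt``: argmin of mean MAE (ties toward larger alpha).
    ``alpha_d_opt`` per condition: argmax of mean d (ties toward smaller
    alpha).  The inverse-relationship flag is set when MAE and d rise
    together across the transition interval (Spearman rho(MAE, d) > 0, i.e.
    accuracy and sensitivity move in opposite directions).
    ``alpha_majority_opt``: the alpha at which the most conditions sit
    within one SE of their own maximum d (ties resolved to the median tied
    alpha).
    """
    alphas = sweep.grid
    mae_mean = (
        sweep.mae_agg.set_index("alpha")["mean_mae"].reindex(alphas).to_numpy()
    )
    if not np.all(np.isfinite(mae_mean)):
        raise ValueError("non-finite aggregate MAE")
    i_mae = len(mae_mean) - 1 - int(np.argmin(mae_mean[::-1]))  # tie -> larger alpha
    alpha_mae_opt = float(alphas[i_mae])

    d_wide = sweep.d_agg.pivot(index="alpha", columns="condition", values="mean_d").reindex(alphas)
    se_wide = sweep.d_agg.pivot(index="alpha", columns="condition", values="se_d").reindex(alphas)
    if not np.all(np.isfinite(d_wide.to_numpy())):
        raise ValueError("non-finite aggregate effect sizes")

    per_condition: dict[str, ConditionRegions] = {}
    within_1se = np.zeros((len(alphas), d_wide.shape[1]), dtype=bool)
    for c, cond in enumerate(d_wide.columns):
        d_curve = d_wide[cond].to_numpy()
        i_d = int(np.argmax(d_curve))  # tie -> smaller alpha (first index)
        alpha_d_opt = float(alphas[i_d])
        lo, hi = sorted((i_mae, i_d))
        if i_d > i_mae and hi - lo >= 1:
            seg_mae, seg_d = mae_mean[lo : hi + 1], d_curve[lo : hi + 1]
            rho = spearmanr(seg_mae, seg_d).statistic if len(seg_mae) > 2 else np.sign(
                (seg_mae[-1] - seg_mae[0]) * (seg_d[-1] - seg_d[0])
            )
            inverse = bool(np.isfinite(rho) and rho > 0)
        else:
            inverse = False
        se_at_max = float(se_wide[cond].to_numpy()[i_d])
        if not np.isfinite(se_at_max):
            se_at_max = 0.0
        within_1se[:, c] = d_curve >= d_curve[i_d] - se_at_max
        per_condition[cond] = ConditionRegions(
            alpha_d_opt=alpha_d_opt,
            d_at_d_opt=float(d_curve[i_d]),
            d_at_mae_opt=float(d_curve[i_mae]),
            mae_at_d_opt=float(mae_mean[i_d]),
            sensitivity_gain=float(d_curve[i_d] - d_curve[i_mae]),
            transition=(float(alphas[lo]), float(alphas[hi])),
            inverse_flag=inverse,
        )

    counts = within_1se.sum(axis=1)
    tied = np.flatnonzero(counts == counts.max())
    alpha_majority_opt = float(alphas[tied[(len(tied) - 1) // 2]])  # lower median, grid-aligned
    return RegionReport(
        alpha_mae_opt=alpha_mae_opt,
        mae_at_opt=float(mae_mean[i_mae]),
        per_condition=per_condition,
        alpha_majority_opt=alpha_majority_opt,
    )


@dataclass
class TrainSizeResult:
    """Train-size analogue of the alpha sweep (CV-selected or fixed alpha)."""

    cells: pd.DataFrame  # size, resample, alpha, mae
    d_cells: pd.DataFrame  # size, condition, resample, d
    mae_agg: pd.DataFrame  # size, mean_mae, se_mae
    d_agg: pd.DataFrame  # size, condition, mean_d, se_d


def run_trainsize_sweep(
    cohort: SyntheticCohort,
    sizes: list[int],
    alpha_policy: str | float = "cv",
    n_resamples: int = 10,
    seed: int = 0,
    grid: AlphaGrid | None = None,
    test_fraction: float = 0.25,
    caliper_sd: float = 0.25,
    study: StudyArms | None = None,
) -> TrainSizeResult:
    """Accuracy and effect size as functions of training-set size.

    ``alpha_policy`` is ``"cv"`` (leave-one-out selection on each training
    resample over ``grid``) or a fixed positive float.
    """
    if grid is None:
        grid = AlphaGrid()
    if not sizes:
        raise ValueError("sizes must be nonempty")
    study_seed, resample_master = _child_seeds(seed, 2)
    if study is None:
        study = prepare_study(cohort, test_fraction, caliper_sd, seed=study_seed)
    pool = len(study.train_pool.subjects)
    if max(sizes) > pool:
        raise ValueError(f"requested size {max(sizes)} exceeds the healthy pool ({pool})")

    Xtr_all = study.train_pool.features.to_numpy()
    ytr_all = study.train_pool.subjects["age"].to_numpy(dtype=float)
    Xte = study.test_pool.features.to_numpy()
    age_te = study.test_pool.subjects["age"].to_numpy(dtype=float)
    healthy_te = ~study.test_pool.is_diagnosed.to_numpy()
    test_index = study.test_pool.subjects.index
    pos = pd.Series(np.arange(len(test_index)), index=test_index)
    pair_pos = {
        cond: (pos[mc.pairs["patient_id"]].to_numpy(), pos[mc.pairs["control_id"]].to_numpy())
        for cond, mc in study.matched.items()
        if mc.n_pairs >= 2
    }

    rows, d_rows = [], []
    for size, size_seed in zip(sizes, _child_seeds(resample_master, len(sizes))):
        for r, rseed in enumerate(_child_seeds(size_seed, n_resamples)):
            rng = np.random.default_rng(rseed)
            take = rng.choice(pool, size=size, replace=False)
            X, y = Xtr_all[take], ytr_all[take]
            if alpha_policy == "cv":
                alpha, _ = select_alpha_cv(X, y, grid)
            else:
                alpha = float(alpha_policy)
            path = RidgePath(X, y, feature_names=cohort.feature_names)
            model = path.model(alpha)
            preds = model.intercept + model.scaler.transform(Xte) @ model.weights
            gaps = make_gap_table(test_index, age_te, preds, np.where(healthy_te, "healthy-test", "patient"))
            corr = fit_bias_correction(gaps)
            corrected = apply_bias_correction(gaps, corr)["corrected_gap"].to_numpy()
            mae = float(np.mean(np.abs(preds[healthy_te] - age_te[healthy_te])))
            rows.append((size, r, alpha, mae))
            for cond, (pp, cp) in pair_pos.items():
                d_rows.append((size, cond, r, cohens_d(corrected[pp], corrected[cp])))

    cells = pd.DataFrame(rows, columns=["size", "resample", "alpha", "mae"])
    d_cells = pd.DataFrame(d_rows, columns=["size", "condition", "resample", "d"])
    return TrainSizeResult(
        cells=cells,
        d_cells=d_cells,
        mae_agg=_aggregate(cells, "mae", ["size"]),
        d_agg=_aggregate(d_cells, "d", ["size", "condition"]),
    )
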