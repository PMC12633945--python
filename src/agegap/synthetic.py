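"""Synthetic cohort generator for brain-age analyses.

Generates tabular cohorts whose statistical structure mirrors the setting in
which brain-age models are trained on imaging-derived phenotypes (IDPs):

* a block of *age features* that track chronological age with high
  signal-to-noise and low residual variance across individuals (think
  regional volumes and contrasts that age very reliably);
* a block of *disease-sensitive features* that load strongly on a shared
  latent **global factor** (the analogue of total gray matter volume) whose
  cross-sectional variance is large relative to its age trend — the kind of
  feature normative models care about and accuracy-optimised age models
  down-weight;
* optional pure-noise features;
* confounders (sex-like, SES-like, deprivation-like, genetic-PC-like) that
  shift both diagnosis propensity and the global factor, so propensity
  matching downstream has real work to do;
* diagnosed conditions that shift the global factor ("global atrophy") and/or
  individual features (focal effects), plus optional *undiagnosed carriers*
  that contaminate the nominally healthy pool with the same effects.

Ground-truth latents (global factor, carrier flags) are kept in a sidecar
table so analysis code cannot accidentally consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ConditionSpec",
    "CovariateSpec",
    "GeneratorConfig",
    "SyntheticCohort",
    "default_conditions",
    "generate_cohort",
    "split_cohort",
]

COVARIATE_NAMES = ("sex", "ses", "deprivation", "pc1", "pc2", "pc3")


class ConfigError(ValueError):
    """Raised when a generator configuration violates an invariant."""


@dataclass(frozen=True)
class ConditionSpec:
    """One diagnosable condition and its effect on the feature-generating model.

    Parameters
    ----------
    name:
        Condition label, used as the 0/1 column name in the cohort table.
    prevalence:
        Target marginal probability of diagnosis, in (0, 0.5).
    global_shift:
        Effect of the condition on the latent global factor, in units of the
        global factor's noise SD (negative = atrophy-like).
    focal_shifts:
        Mapping from feature name to an additive raw-unit shift for cases
        (localised effects).
    confounding_strength:
        Multiplier on the covariate block of the diagnosis log-odds; 0 makes
        diagnosis independent of the confounders.
    """

    name: str
    prevalence: float
    global_shift: float = 0.0
    focal_shifts: Mapping[str, float] = field(default_factory=dict)
    confounding_strength: float = 1.0


@dataclass(frozen=True)
class CovariateSpec:
    """Confounder distributions and their pathways into diagnosis and features.

    Covariates are fixed in form: ``sex`` ~ Bernoulli(0.5), and ``ses``,
    ``deprivation``, ``pc1..pc3`` ~ standard normal.  ``diagnosis_log_odds``
    holds per-covariate slopes on each condition's diagnosis log-odds (scaled
    by that condition's ``confounding_strength``); ``age_log_odds_per_year``
    is the age slope of diagnosis risk (always applied); and
    ``global_factor_effects`` are additive effects of covariates on the
    latent global factor, in global-factor units.
    """

    diagnosis_log_odds: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex": 0.3,
            "ses": -0.3,
            "deprivation": 0.4,
            "pc1": 0.15,
            "pc2": -0.1,
            "pc3": 0.1,
        }
    )
    age_log_odds_per_year: float = 0.05
    global_factor_effects: Mapping[str, float] = field(
        default_factory=lambda: {"sex": 0.25, "ses": 0.15, "deprivation": -0.3}
    )


def default_conditions(n_age_features: int = 50, n_disease_features: int = 8) -> list[ConditionSpec]:
    """Default three-condition panel emulating cross-condition variety.

    Two conditions act through the global factor at different strengths
    (diffuse, atrophy-like changes); the third acts focally on a handful of
    age-informative features, pushing each in the direction that feature
    normally moves with aging (an accelerated-aging signature confined to a
    few regions), so its effect is visible to accuracy-optimised models and
    its effect size peaks at intermediate regularization.
    """
    focal: dict[str, float] = {}
    for j in range(2, min(8, n_age_features)):
        sign = 1.0 if j % 2 == 0 else -1.0  # matches the default loading signs
        focal[_feature_name(j)] = 0.8 * sign
    return [
        ConditionSpec("global_strong", prevalence=0.02, global_shift=-0.8),
        ConditionSpec("global_weak", prevalence=0.05, global_shift=-0.4),
        ConditionSpec("focal", prevalence=0.03, focal_shifts=focal),
    ]


def _feature_name(index: int) -> str:
    return f"f{index + 1:04d}"


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort generator.

    The defaults are the package's reference study conditions: 50 age
    features, 8 disease-sensitive features, 2 noise features, three
    conditions, mild confounding and 5% contamination of the healthy pool.
    """

    n_subjects: int = 20_000
    age_min: float = 45.0
    age_max: float = 80.0
    n_age_features: int = 50
    n_disease_features: int = 8
    n_noise_features: int = 2
    age_loadings: np.ndarray | None = None
    global_factor_sd: float = 2.0
    global_age_slope: float = -0.12
    age_feature_noise_sd: float = 1.0
    disease_feature_noise_sd: float = 2.0
    age_feature_global_loading: float = 0.05
    disease_feature_global_loading: float = 1.0
    disease_feature_age_slope: float = 0.01
    conditions: Sequence[ConditionSpec] | None = None
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    contamination_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conditions is None:
            self.conditions = default_conditions(self.n_age_features, self.n_disease_features)
        if self.age_loadings is None:
            # Alternating-sign per-year slopes: brain features may grow or
            # shrink with age; magnitudes span a plausible SNR range.
            mags = np.linspace(0.04, 0.10, self.n_age_features)
            signs = np.where(np.arange(self.n_age_features) % 2 == 0, 1.0, -1.0)
            self.age_loadings = mags * signs
        else:
            self.age_loadings = np.asarray(self.age_loadings, dtype=float)

    # -- derived layout ---------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.n_age_features + self.n_disease_features + self.n_noise_features

    @property
    def feature_names(self) -> list[str]:
        return [_feature_name(j) for j in range(self.n_features)]

    @property
    def feature_groups(self) -> dict[str, list[str]]:
        names = self.feature_names
        na, nd = self.n_age_features, self.n_disease_features
        return {
            "age": names[:na],
            "disease": names[na : na + nd],
            "noise": names[na + nd :],
        }

    def validate(self) -> None:
        """Check all invariants; raise :class:`ConfigError` naming the violation."""
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be > 0")
        if self.n_age_features <= 0:
            raise ConfigError("n_age_features must be > 0")
        if self.n_disease_features <= 0:
            raise ConfigError("n_disease_features must be > 0")
        if self.n_noise_features < 0:
            raise ConfigError("n_noise_features must be >= 0")
        if not self.age_min < self.age_max:
            raise ConfigError("age_min must be < age_max")
        for name in ("global_factor_sd", "age_feature_noise_sd", "disease_feature_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.age_feature_noise_sd >= self.disease_feature_noise_sd:
            raise ConfigError(
                "age_feature_noise_sd must be < disease_feature_noise_sd "
                "(age features are the low-residual-variance block by construction)"
            )
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ConfigError("contamination_rate must be in [0, 1)")
        if len(self.age_loadings) != self.n_age_features:
            raise ConfigError("age_loadings length must equal n_age_features")
        if not self.conditions:
            raise ConfigError("at least one condition must be specified")
        seen: set[str] = set()
        valid_features = set(self.feature_names)
        for cond in self.conditions:
            if not 0.0 < cond.prevalence < 0.5:
                raise ConfigError(f"prevalence of condition {cond.name!r} must be in (0, 0.5)")
            if cond.name in seen:
                raise ConfigError(f"duplicate condition name {cond.name!r}")
            seen.add(cond.name)
            unknown = set(cond.focal_shifts) - valid_features
            if unknown:
                raise ConfigError(
                    f"focal_shifts of condition {cond.name!r} reference unknown features {sorted(unknown)}"
                )


@dataclass
class SyntheticCohort:
    """A generated (or loaded) cohort.

    ``subjects`` holds id, age, covariates and 0/1 condition labels;
    ``features`` the feature matrix (same index); ``truth`` the hidden
    per-subject latents (global factor, its noise, carrier flags) — test-only
    and written to a separate sidecar file so analysis stages never see it.
    ``truth`` is ``None`` for user-supplied real data.
    """

    subjects: pd.DataFrame
    features: pd.DataFrame
    truth: pd.DataFrame | None
    covariate_names: list[str]
    condition_names: list[str]
    feature_groups: dict[str, list[str]]
    config: GeneratorConfig | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def is_diagnosed(self) -> pd.Series:
        """Boolean per subject: carries at least one diagnosed condition."""
        if not self.condition_names:
            return pd.Series(False, index=self.subjects.index)
        return self.subjects[self.condition_names].any(axis=1)

    def subset(self, index: pd.Index) -> "SyntheticCohort":
        return SyntheticCohort(
            subjects=self.subjects.loc[index].copy(),
            features=self.features.loc[index].copy(),
            truth=None if self.truth is None else self.truth.loc[index].copy(),
            covariate_names=list(self.covariate_names),
            condition_names=list(self.condition_names),
            feature_groups={k: list(v) for k, v in self.feature_groups.items()},
            config=self.config,
        )


def _calibrate_intercept(linear_predictor: np.ndarray, prevalence: float) -> float:
    """Solve for the logistic intercept giving the target mean probability."""

    def gap(b: float) -> float:
        return float(expit(linear_predictor + b).mean() - prevalence)

    lo, hi = -40.0, 40.0
    return brentq(gap, lo, hi, xtol=1e-10)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a cohort from the generative model.  Deterministic given ``config.seed``.

    Model, per subject i:

    * age_i ~ Uniform(age_min, age_max)
    * covariates: sex ~ Bernoulli(0.5); ses, deprivation, pc1..3 ~ N(0, 1)
    * condition c: logit P(diagnosed) = b_c + s_c * (covariate slopes) +
      age slope * (age - mean age), with b_c calibrated numerically so the
      marginal prevalence matches the spec'd target
    * undiagnosed carriers: each subject with no diagnosis becomes a hidden
      carrier of one condition (chosen with probability proportional to
      prevalence) with probability ``contamination_rate``
    * global factor g_i = age slope * (age - mid age) + covariate effects +
      sum of global shifts (diagnosed or carried) * global_factor_sd +
      N(0, global_factor_sd)
    * age feature j = a_j * age + lambda_age * g + N(0, age_feature_noise_sd)
    * disease feature k = weak age trend + lambda_dis * g + focal shifts +
      N(0, disease_feature_noise_sd)
    * noise features ~ N(0, 1)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    age_mid = 0.5 * (config.age_min + config.age_max)

    age = rng.uniform(config.age_min, config.age_max, size=n)
    cov = pd.DataFrame(
        {
            "sex": (rng.random(n) < 0.5).astype(float),
            "ses": rng.standard_normal(n),
            "deprivation": rng.standard_normal(n),
            "pc1": rng.standard_normal(n),
            "pc2": rng.standard_normal(n),
            "pc3": rng.standard_normal(n),
        }
    )

    cov_spec = config.covariates
    cov_lp = np.zeros(n)
    for name, w in cov_spec.diagnosis_log_odds.items():
        cov_lp += w * cov[name].to_numpy()
    age_lp = cov_spec.age_log_odds_per_year * (age - age.mean())

    conditions = list(config.conditions)
    labels = {}
    for cond in conditions:
        lp = cond.confounding_strength * cov_lp + age_lp
        b = _calibrate_intercept(lp, cond.prevalence)
        labels[cond.name] = (rng.random(n) < expit(lp + b)).astype(int)
    label_df = pd.DataFrame(labels)
    diagnosed = label_df.to_numpy().any(axis=1)

    # Undiagnosed carriers among the nominally healthy.
    carrier = np.zeros(n, dtype=bool)
    carrier_condition = np.full(n, "", dtype=object)
    if config.contamination_rate > 0:
        healthy = ~diagnosed
        carrier = healthy & (rng.random(n) < config.contamination_rate)
        prev = np.array([c.prevalence for c in conditions])
        picks = rng.choice(len(conditions), size=n, p=prev / prev.sum())
        carrier_condition[carrier] = [conditions[k].name for k in picks[carrier]]

    # Effective condition effects (diagnosed cases plus hidden carriers).
    global_shift = np.zeros(n)
    focal = np.zeros((n, config.n_features))
    name_to_col = {name: j for j, name in enumerate(config.feature_names)}
    for cond in conditions:
        affected = label_df[cond.name].to_numpy().astype(bool) | (carrier_condition == cond.name)
        global_shift += affected * cond.global_shift
        for fname, shift in cond.focal_shifts.items():
            focal[affected, name_to_col[fname]] += shift

    g_noise = rng.normal(0.0, config.global_factor_sd, size=n)
    g = (
        config.global_age_slope * (age - age_mid)
        + sum(
            w * cov[name].to_numpy() for name, w in cov_spec.global_factor_effects.items()
        )
        + global_shift * config.global_factor_sd
        + g_noise
    )

    X = np.empty((n, config.n_features))
    na, nd = config.n_age_features, config.n_disease_features
    X[:, :na] = (
        age[:, None] * config.age_loadings[None, :]
        + config.age_feature_global_loading * g[:, None]
        + rng.normal(0.0, config.age_feature_noise_sd, size=(n, na))
    )
    X[:, na : na + nd] = (
        config.disease_feature_age_slope * age[:, None]
        + config.disease_feature_global_loading * g[:, None]
        + rng.normal(0.0, config.disease_feature_noise_sd, size=(n, nd))
    )
    if config.n_noise_features:
        X[:, na + nd :] = rng.standard_normal((n, config.n_noise_features))
    X += focal

    index = pd.Index([f"S{i + 1:06d}" for i in range(n)], name="subject_id")
    subjects = pd.concat(
        [pd.Series(age, name="age"), cov, label_df], axis=1
    ).set_index(index)
    features = pd.DataFrame(X, index=index, columns=config.feature_names)
    truth = pd.DataFrame(
        {
            "global_factor": g,
            "global_noise": g_noise,
            "is_carrier": carrier.astype(int),
            "carrier_condition": carrier_condition,
        },
        index=index,
    )
    return SyntheticCohort(
        subjects=subjects,
        features=features,
        truth=truth,
        covariate_names=list(COVARIATE_NAMES),
        condition_names=[c.name for c in conditions],
        feature_groups=config.feature_groups,
        config=config,
    )


def split_cohort(
    cohort: SyntheticCohort,
    test_fraction: float,
    seed: int,
    min_train: int | None = None,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Split into a healthy-only training pool and a mixed test pool.

    Diagnosed subjects never enter the training pool; hidden carriers (no
    diagnosis) stay in it, which is exactly the contamination pathway.  The
    test pool contains all diagnosed subjects plus a random
    ``test_fraction`` of the healthy subjects.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    diagnosed = cohort.is_diagnosed.to_numpy()
    healthy_idx = cohort.subjects.index[~diagnosed]
    n_test_healthy = int(round(test_fraction * len(healthy_idx)))
    held = rng.choice(len(healthy_idx), size=n_test_healthy, replace=False)
    held_mask = np.zeros(len(healthy_idx), dtype=bool)
    held_mask[held] = True
    train_ids = healthy_idx[~held_mask]
    test_ids = cohort.subjects.index[diagnosed].append(healthy_idx[held_mask])
    if min_train is not None and len(train_ids) < min_train:
        raise ValueError(
            f"training pool has {len(train_ids)} healthy subjects, "
            f"{min_train - len(train_ids)} short of the requested {min_train}"
        )
    return cohort.subset(train_ids), cohort.subset(test_ids)
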