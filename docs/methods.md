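# Methods

## 1. Problem setting

A brain-age model compresses a vector of imaging-derived phenotypes (IDPs)
into one scalar trained to minimise chronological-age error.  The package
studies a specific failure mode of that objective: features with large
cross-sectional variance — typically global measures such as total gray
matter volume, which are also the features most sensitive to diffuse
pathology — are down-weighted relative to low-variance, high-age-SNR
features, because their variance is "noise with respect to age".  The
resulting brain-age gaps can be very accurate about age and nearly blind to
disease.  Over-regularising the linear model reverses the weighting:
accuracy falls, patient-control effect sizes rise.

Everything in the package is organised to measure that trade-off under
known ground truth.

## 2. The synthetic cohort generator

### Generative model

Per subject *i* (all noise independent Gaussian unless stated):

1. `age_i ~ Uniform(age_min, age_max)`, default 45–80 years (a typical
   population-imaging age window; configurable).
2. Covariates: `sex ~ Bernoulli(0.5)`; `ses`, `deprivation`,
   `pc1..pc3 ~ N(0,1)` (socioeconomic-status-like, deprivation-index-like,
   and genetic-principal-component-like confounders).
3. Diagnosis, per condition c:
   `logit P = b_c + s_c·(covariate slopes) + 0.05·(age − mean age)`,
   with the intercept `b_c` solved numerically (Brent) so the marginal
   prevalence hits its target.  `s_c` is the condition's
   `confounding_strength`; the age slope makes patients older on average,
   so both matching and bias correction have real confounding to remove.
4. Hidden global factor (the total-gray-matter-volume analogue):
   `g_i = γ·(age − mid age) + covariate effects + Σ_c shift_c·σ_g·affected_ic + N(0, σ_g)`
   with `σ_g = 2.0` and age slope `γ = −0.12 / year` — a ≈2 SD decline
   across the age range, the scale of lifetime gray-matter loss.  The noise
   term is the *cross-sectional variance* the mechanism is about: it is
   shared across all disease-sensitive features and does not average out.
5. Features (60 by default, named `f0001`…):
   - 50 age features: `a_j·age + 0.05·g + N(0, 1.0)`.  Loadings `a_j`
     alternate in sign with |a_j| ∈ [0.04, 0.10] per year, so individual
     age correlations span ≈0.4–0.7 — reliable, low-residual-variance
     aging markers (pons-volume-like).
   - 8 disease features: `0.01·age + 1.0·g + focal shifts + N(0, 2.0)`.
     High variance, strongly loaded on the shared factor, weak direct age
     information (their age signal is mostly *via* g).
   - 2 pure-noise features: `N(0, 1)`.
6. Contamination: each undiagnosed subject carries, with probability
   `contamination_rate` (default 0.05), the full effect of one condition
   (chosen proportionally to prevalence) without the label — the
   "undiagnosed cases in the healthy training pool" pathway.  Carrier flags
   live only in the hidden-truth sidecar.

### Default condition panel

| condition | prevalence | effect |
|---|---|---|
| `global_strong` | 0.02 | −0.8 σ_g on the global factor (marked diffuse atrophy) |
| `global_weak` | 0.05 | −0.4 σ_g on the global factor |
| `focal` | 0.03 | +0.8 raw units on six age features (f0003–f0008), each shift sign-aligned with that feature's age loading |

The focal condition is an accelerated-aging signature confined to a few
age-informative regions.  Two design points matter.  First, the shifts are
sign-aligned with the loadings: a shift pattern orthogonal to the aging
direction is invisible to *any* linear age model, aligned shifts are the
detectable case.  Second, this condition is the one whose effect size peaks
at an *intermediate* α: its signal lives where the accuracy-optimised model
already looks, so it gains little from over-regularization and eventually
loses as weight mass migrates to the global factor.  The two global
conditions peak at the top of the grid.  This reproduces the qualitative
cross-condition variety of the phenomenon (regime boundaries differ by the
anatomy of the effect).

The free mechanism parameters not dictated by the scenario description
(γ = −0.12/yr and the focal magnitude 0.8) were fixed during generator
design so that each qualitative regime — the inversion for global
conditions, the interior peak for the focal one — is decisively resolved at
the default study size (n = 20,000 subjects, 5,000 training subjects, 10
resamples) rather than decided by seed noise; they were then frozen.

### What the generator does not emulate

Linear feature-age relationships only (no nonlinear aging trajectories); no
spatial or hierarchical structure among features; a single global factor
(real IDP covariance has many); Gaussian noise (no site effects, scanner
drift, heavy tails); cross-sectional only; conditions act additively and
instantaneously (no progression, no diagnosis-to-scan lag).  Consequently,
passing results demonstrate that the pipeline detects the variance
mechanism when it is present and calibrated under the null — they do not
quantify effect sizes, optimal α values, or MAEs expected in any real
cohort.

## 3. Pipeline stages

**Split.**  Diagnosed subjects never enter training.  The test pool is all
patients plus a random 25% of the healthy subjects; the remaining healthy
subjects form the training pool (hidden carriers included — that is the
contamination pathway).

**Ridge model.**  Features are standard-scaled with statistics of the
training resample only; the weights solve `(XᵀX + αI)w = Xᵀ(y − ȳ)` on the
scaled, centred data and the intercept is the training age mean.
Numerically the solve goes through one thin SVD of the scaled design,
which is stable at extreme α and makes the whole 100-point grid (10⁻⁵…10⁵,
log-spaced) essentially one decomposition per resample.  Zero-variance
features are rejected by name (tolerance `sd ≤ 1e-10·max(1, |mean|)`, since
a constant column has floating-point sd ≈ eps·|mean|, not 0).  α = 0 on a
rank-deficient design raises with the instruction to use α > 0.

**α selection.**  Default is exact leave-one-out via the hat-diagonal
identity `e_i = r_i/(1 − h_ii)`, computed from the same SVD with the
unpenalized intercept included in the hat matrix; data are scaled once on
the full training sample, so the identity is exact against a naive
refit-per-row oracle.  The k-fold option refits the scaler inside every
fold (no leakage).  CV-error ties break toward larger α (more shrinkage,
deterministic).

**Bias correction.**  OLS of raw gap on age, fitted by default on *all*
test rows — patients and healthy test subjects pooled.  Whether the
correction should pool patients is genuinely ambiguous in practice; the
pooled fit is the default and a `healthy_only` switch exists for
sensitivity analysis.  The correction is fitted once per trained model per
test set and frozen for all group comparisons.  On the fitting sample the
residuals are mean-zero and age-orthogonal to machine precision, which is
asserted in the acceptance suite.

**Matching.**  Logistic propensity model (statsmodels MLE) on age plus all
covariates; scores on the logit scale.  The caliper is 0.25 × SD of the
pooled logit scores — the Rosenbaum–Rubin convention; a probability-scale
caliper would conflate score location with spread.  Matching is greedy 1:1
nearest-neighbour without replacement, patient order randomized by a fixed
derived seed; greedy is the common default, is O(n log n), and its
determinism given the seed is tested.  Controls are drawn only from healthy
test-pool subjects.  Balance is reported as standardized mean differences
with the pre-match pooled SD as the denominator for both stages (one
scale).  Matched cohorts are built once per cohort and reused across every
α and training resample, so the model is the only varying factor in the
sweep.

**Effect size.**  Cohen's d with the pooled-SD denominator (the default
textbook definition; Hedges' small-sample factor available via flag),
positive = patients older-appearing.  Bootstrap SE resamples within each
group (default 1,000 draws); degenerate resamples with zero pooled SD are
redrawn and counted.  In sweeps, uncertainty is instead the SE over
training resamples, matching the repeated-subsampling convention.

**Sweep and regime identification.**  Per training resample (default 10
resamples of 5,000 healthy subjects): fit the path, predict the full test
pool, fit+apply the bias correction per α, record MAE on healthy test
subjects only, and matched d per condition.  `alpha_mae_opt` is the argmin
of mean MAE (tie → larger α); `alpha_d_opt` per condition the argmax of
mean d (tie → smaller α); curves are used unsmoothed, with SE bands
reported so users can judge flatness.  The transition interval is the α
range between the two optima; the inverse-relationship flag is set when
Spearman ρ(MAE, d) > 0 over that interval, i.e. error and effect size rise
together (accuracy and sensitivity anti-correlated).  `alpha_majority_opt`
operationalises "the α maximising effect sizes for a majority of
conditions": the α at which the most conditions lie within one SE of their
own maximum d, ties resolved to the lower-median tied α (always
grid-aligned).

**Attribution.**  For a linear model the Shapley value under the
independent-features convention is exact and closed-form:
φ_ij = w_j·(z_ij − mean background z_j) on the scaled space, equal to
`(w_j/s_j)(x_ij − x̄_j)` in raw units; attributions are in years and sum to
prediction − mean background prediction (tested at 1e−8, and against a full
2¹⁰-coalition enumeration at 1e−6).  The background is the healthy training
sample of each resample (the normative reference population); attributions
are computed on healthy test subjects — importance *for age prediction* —
and averaged over resamples.  Because |φ| factorises for linear models,
per-α importances cost one |w| multiplication after a single pass over the
samples.  "Relative" importances are normalised by the per-α maximum.  The
`global_mass(α)` curve is the fraction of total mean |φ| carried by the
disease-sensitive feature block; 0/0 (all-zero weights) is reported as NaN
with a warning.

**Orchestration.**  One master seed; per-stage and per-resample integer
seeds are derived through `numpy.random.SeedSequence` and never shared.
All artifacts are CSV/JSON/YAML with a fixed float format, so identical
configs produce byte-identical outputs (tested).  For user-supplied cohort
CSVs, rows with missing values are excluded per analysis stage — a row
missing a feature value is dropped from model fitting but still usable by
stages that need only age and labels — with dropped counts logged.

## 4. Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the default scenario
(20,000 subjects, 60 features, 5,000 training subjects, 100-point grid, 10
resamples) over 10 master seeds, which resolves all three qualitative
regimes in seconds per seed thanks to the SVD path.  The null-calibration
runs use 60,000 subjects with 2 resamples: under the null the resample axis
only averages model noise, while matched-cohort sampling noise
(≈ √(2/n_pairs)) dominates, so the cohort is sized to give every condition
well over 400 matched pairs and keep the |d| < 0.15 calibration bound a
≈4-sigma event rather than a coin flip.

## 5. Known limitations

- Greedy caliper matching is not optimal matching; occasional post-match
  SMDs marginally above 0.1 occur for strongly confounded conditions.
- The inverse-relationship flag and regime boundaries are argmin/argmax of
  unsmoothed mean curves; on flat plateaus the located optimum can move by
  a few grid ticks between seeds (the SE bands are the guide).
- `d` uses the pooled SD; with strongly unequal group variances Glass's Δ
  would differ (not implemented).
- The propensity model is linear-logistic; non-linear confounding would
  require a richer score model than the package provides.
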