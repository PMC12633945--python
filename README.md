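# agegap

Brain-age models are regression models that predict a person's chronological
age from brain imaging features; the residual — the **brain-age gap**
(predicted minus true age, after a sample-level bias correction) — is widely
used as a biomarker of brain health.  The conventional wisdom is that a more
accurate age model makes a better biomarker.  `agegap` is a library for
studying why that is often false for linear models: optimising age-prediction
accuracy drives a ridge model toward features with high age signal-to-noise
and low residual variance across individuals, and away from high-variance
global measures (total gray-matter-volume-like factors) that carry most of
the disease signal.  Over-regularising the model degrades age accuracy but
*increases* patient-vs-control effect sizes of the gap.

The package is aimed at researchers in normative modelling and brain-age
methodology.  It provides:

- **`synthetic`** — a cohort generator whose latent structure encodes the
  variance mechanism (age-informative low-variance features, a global factor
  with large cross-sectional variance, confounders driving both diagnosis
  and features, optional contamination of the healthy pool with undiagnosed
  carriers), with ground-truth latents in a sidecar table;
- **`ridge`** — standard-scaled ridge regression of age on features with the
  100-point log-spaced α grid (10⁻⁵…10⁵) and exact leave-one-out /
  k-fold α selection;
- **`bias`** — sample-level linear bias correction: OLS of raw gap on age
  over the test sample, analyses on the residuals;
- **`matching`** — logistic propensity scores, greedy 1:1 nearest-neighbour
  matching without replacement with a 0.25-SD logit caliper, SMD balance
  diagnostics;
- **`effects`** — pooled-SD Cohen's *d* (positive = patients older-appearing)
  with a within-group bootstrap SE;
- **`sweep`** — the regularization sweep (resampled training sets, per-α MAE
  on healthy test subjects and per-condition matched *d*), identification of
  the accuracy-optimal / transition / detection-optimal regimes, and a
  train-size sweep;
- **`attribution`** — exact linear SHAP values (closed form for linear
  models), top-k rankings, and the global-attribution-mass curve;
- **`pipeline` / CLI** — end-to-end reproducible experiments
  (`agegap run-all`, `generate`, `match`, `sweep`, `attribute`, `report`).

## The model

With standardized features X and ages y, the age model solves

    (XᵀX + αI) w = Xᵀ(y − ȳ),    prediction = ȳ + x·w

Raw gaps g = ŷ − y are corrected by OLS on age over all test subjects,
g* = g − (â + b̂·age).  For each condition, patients are 1:1
propensity-matched to healthy test controls (caliper 0.25 SD of the logit
score) and separation is measured as Cohen's
d = (mean g*₁ − mean g*₀) / pooled SD.  Sweeping α maps MAE(α) against
d(α); the accuracy optimum (argmin MAE) and the detection optimum
(argmax d) disagree, with an intermediate transition region in which MAE
rises while d rises.  Exact SHAP attributions φᵢⱼ = wⱼ(xᵢⱼ − x̄ⱼ)
show the attribution mass moving onto the global-factor features as α grows.

## Worked example

```python
from agegap import GeneratorConfig, generate_cohort, run_alpha_sweep, identify_regions

cohort = generate_cohort(GeneratorConfig(seed=1))          # 20,000 subjects, 60 features
sweep = run_alpha_sweep(cohort, n_train=5000, n_resamples=10, seed=1)
regions = identify_regions(sweep)
print(f"accuracy-optimal alpha: {regions.alpha_mae_opt:.3g}  (MAE {regions.mae_at_opt:.2f} y)")
for cond, r in regions.per_condition.items():
    print(f"{cond:>14}: d = {r.d_at_mae_opt:+.2f} at the accuracy optimum -> "
          f"{r.d_at_d_opt:+.2f} at alpha = {r.alpha_d_opt:.3g} (MAE there {r.mae_at_d_opt:.2f} y)")
print(f"majority detection optimum: alpha = {regions.alpha_majority_opt:.3g}")
```

prints

```
accuracy-optimal alpha: 599  (MAE 1.54 y)
         focal: d = +0.41 at the accuracy optimum -> +0.48 at alpha = 1.56e+04 (MAE there 2.00 y)
 global_strong: d = +0.22 at the accuracy optimum -> +0.50 at alpha = 1e+05 (MAE there 4.79 y)
   global_weak: d = +0.08 at the accuracy optimum -> +0.24 at alpha = 1e+05 (MAE there 4.79 y)
majority detection optimum: alpha = 1e+05
```

Reading: the most accurate model (MAE 1.5 years) barely separates patients
with a diffuse global effect from matched controls (d ≈ 0.1–0.2); pushing α
two orders of magnitude past the accuracy optimum triples the age error but
more than doubles the effect sizes for the global-effect conditions.  The
focal condition — whose effect sits in a few age-informative regions rather
than the global factor — peaks at an intermediate α instead: the balance
point varies across conditions.

The same run from a shell:

```bash
agegap run-all --out runs/demo --seed 1 --plots
```

writes the cohort, matched pairs, sweep tables, attribution tables, region
report and figures under `runs/demo/`.

## Limitations

The generator is a deliberately low-dimensional, linear, cross-sectional
stand-in for real imaging-derived phenotypes; see `docs/methods.md` for the
full model, parameter rationale, and what the synthetic results do and do
not establish about real cohorts.
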