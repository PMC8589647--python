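# Methods

## Normative brain-age model

The model is a ridge regression of chronological age on p standardized
morphometric features, fit in healthy controls only and separately per
sex (male and female models never share scaler statistics or
coefficients). Features are z-scored with training-sample means and SDs
— ridge is scale-sensitive and the feature set mixes mm (thickness),
mm² (area) and mm³ (volumes) — and the scaler travels with the model, so
prediction is the affine map

    ŷ = β0 + Σ_f β_f (x_f − mean_f) / sd_f .

The default penalty is λ = 1 on the standardized scale; with n ≈ 1000
training controls and p = 77 the fit is close to OLS and the results are
insensitive to λ over several orders of magnitude. Model files are
versioned JSON; prediction aligns features by name, so column order is
irrelevant, and a missing feature is an error rather than a silent
default.

Performance is quantified by tenfold cross-validation with metrics
computed on the pooled out-of-fold predictions (a single MAE/SD pair,
Pearson r, and R²), not per-fold averages. A dimensionless
`scaled_mae = MAE / (age_hi − age_lo)` is exposed for comparing models
trained on different age ranges; the raw ratio is reported without any
convention about inclusive/exclusive range widths.

### Shrinkage bias and its consequences

Any regression-based age predictor is a shrinkage estimator: the slope
of ŷ on age in held-out controls is below 1 (approximately the
population R² of age given the features), so young subjects are
overpredicted and old subjects underpredicted. Two consequences matter
here:

1. **Bias handling.** Case–control inference must not compare groups
   with different age distributions on raw brain-PAD. We follow the
   covariate approach: age and age² enter the mixed model as fixed
   effects (centered at the pooled test mean before squaring, to
   decorrelate the linear and quadratic terms). Predictions themselves
   are never rescaled.
2. **Attenuation of group shifts.** A group difference generated as an
   age shift of Δ years inside the feature mean function is transduced
   to a brain-PAD difference of roughly s·Δ, where s (< 1) is the
   held-out prediction slope. At the packaged operating point
   (R² ≈ 0.72) the recovered diagnosis coefficient for Δ = 1.08 years is
   ≈ 0.8 years. This regression dilution is a property of the
   estimand, not an estimation error: the age covariates remove the
   age-related bias from the contrast but cannot restore the attenuated
   signal. Interpreting an observed brain-PAD difference as an
   underestimate of the underlying "brain-age gap" by a factor ≈ R² is
   therefore appropriate whenever the generative effect is an
   age-trajectory shift.

## Mixed-model inference

Pooled (both sexes) held-out brain-PAD values are modelled with a linear
mixed model carrying a Gaussian random intercept per scanning site and
i.i.d. Gaussian residuals. The full fixed-effect structure is
Dx, sex, age, age², Dx×age, Dx×sex, age×sex, Dx×age×sex; interactions
are pruned top-down by backward elimination at α = 0.05 (three-way
first, then the two Dx two-ways), ending at the main-effects model when
nothing survives. Fits use REML for reporting and ML refits for
likelihood-ratio tests (the LRT reports its df explicitly as the number
of added fixed parameters). Fixed effects are tested with two-sided
Wald z tests — samples are in the thousands, so small-sample df
corrections are out of scope.

Estimation notes: statsmodels' MixedLM optimizer can pin σ_u² to the
boundary and return a degenerate likelihood; the fit tries BFGS, then
L-BFGS and Powell, and if all degenerate falls back to OLS with
σ_u² = 0, flagging the result as `boundary` (this is the exact
zero-site-variance limit, and also covers single-site data, where the
random intercept is unidentifiable). Constant outcomes short-circuit to
a zero-variance result rather than an optimizer failure.

The diagnosis effect is standardized as Cohen's
d = β̂(Dx) / √(σ̂_u² + σ̂_ε²) — the model's total residual SD is the
natural two-group pooled SD after covariate adjustment — with
SE_d = √((n1+n2)/(n1·n2) + d²/(2(n1+n2))) and a normal 95% CI. This
construction reproduces published SE/CI arithmetic exactly at the
corresponding group sizes (e.g. d = 0.14 with n = 2126/2675 gives
SE 0.03 and CI 0.08–0.20).

Clinical subgroups (first/recurrent episode, current/remitted,
antidepressant user/free, early/middle/late onset — 10 contrasts against
all test controls) are each fit with the main-effects model; the 10
contrasts plus the 2 continuous severity slopes (HDRS-17, BDI-II, fit
within patients) form a single Benjamini–Hochberg FDR family. Pairwise
patient-only contrasts are reported post hoc, uncorrected. Subgroups
with fewer than 10 members are flagged `low_n`.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions under which every downstream claim is verified. Each of 77
averaged feature archetypes follows

    x_f = μ_f + a_f(age* − 40) + q_f(age* − 40)² + s_f[male]
          + γ_f(ICV − ICV̄) + u_fj + ε,
    age* = age + Δ·[MDD],  u_fj ~ N(0, τ_f²),  ε ~ N(0, (c·σ_f)²),

and is split into left/right measures by a per-feature offset plus
per-person antisymmetric noise, so hemisphere averaging recovers the
archetype value exactly. Design choices:

- **Diagnosis effect as an age shift.** Δ (default 1.08 years) enters
  the mean function as added age, so any consistent age predictor
  transduces it to brain-PAD — the construct of an "older-appearing
  brain" — subject to the attenuation discussed above.
- **Composition.** 22 sites totalling 4314 controls (1879 m / 2435 f)
  and 2675 patients (986 m / 1689 f), with male participants at 16 of
  the 22 sites; per-site counts are spread nearly evenly, as site-level
  breakdowns are not public.
- **Ages** are truncated normal on [18, 75] whose *observed* mean/SD
  match the target stratum values (controls m 43.1 [15.3], f 39.4
  [15.7]; patients m 42.8 [13.1], f 43.2 [14.0]); the generator solves
  for the parent parameters, since truncation otherwise shrinks the SD
  by ~20%. The female-control target sits near the feasibility edge of
  a truncated normal on this support and resolves to an observed SD of
  ~15.1.
- **Trajectory signs.** Cortical thickness declines with age
  (standardized slopes the strongest of the three cortical/subcortical
  modalities), except entorhinal and temporal pole; surface areas
  decline weakly; subcortical volumes decline moderately; lateral
  ventricles expand. Quadratic terms (q_f = a_f/100) make aging
  accelerate, which is what the quadratic-age-covariate LRT detects
  downstream. ICV carries no age trend and couples into volumes/areas.
- **Noise calibration.** A single global multiplier c scales all
  feature noise. It was frozen once at c = 1.08 by a grid search
  (`scripts/calibrate_noise.py`) targeting a female tenfold-CV MAE of
  ≈ 6.6 years and R² ≈ 0.72; the resulting corrected within-group
  brain-PAD SD is ≈ 6.6 years. A larger target SD (≈ 7.7) is not
  jointly reachable with that MAE under this error budget, because the
  same noise drives both.
- **Clinical labels** are drawn independently of the features
  (homogeneous-effect default) with proportions among patients of
  903/2675 first-episode, 1648 recurrent, 1786 current, 298 remitted,
  1717 antidepressant users, 939 free, and 1035/1218/259
  early/middle/late onset; the remainders on each axis are drawn as
  unrecorded ("unknown"), mirroring real-data missingness. Onset
  categories are restricted to those feasible at the participant's age
  (late onset requires age > 55), so realized late-onset counts fall
  below the nominal proportion in younger samples. Severity scores are
  zero-inflated discretized normals within scale bounds (HDRS-17 0–52,
  BDI-II 0–63), independent of the brain features.
- **Determinism.** A single seed fans out to fixed-order substreams
  (demographics, site offsets, feature noise, labels); identical
  (config, seed) yields byte-identical output.

What the generator does **not** emulate: residual spatial covariance
between regions beyond the shared age/site/ICV factors, scanner
field-strength effects, non-Gaussian feature distributions
(ventricle volumes are right-skewed in reality; here a small positive
floor clips the Gaussian tail), and any dependence of clinical labels
or severity on brain structure. Passing tests therefore demonstrate
correctness of the machinery and recoverability of effects under these
idealized conditions, not performance on real scanner data.

## Partition and QC

Controls are split 50:50 within each site × sex cell, stratified on
5-year age bins (configurable); odd bins alternate the extra participant
starting with train, keeping the cell imbalance ≤ 1. All patients go to
the test side. The 10-control floor is applied per sex, because the
normative models are sex-specific; an excluded cell drops its patients
too. Assignments are invariant to input row order (rows are sorted by
participant id before sampling).

QC flags cells with within-sex |z| > 6 per feature and then applies a
complete-case policy — at 6 SD only corrupt records are removed, and the
prediction model has no missing-data mechanism, so imputation is
deliberately avoided. Surviving values are never altered.

## Interpretation analyses

Ridge weights on correlated features do not support regional
interpretation, so importance is summarized by (1) structure
coefficients — Pearson correlations between predicted brain age and
each feature, computed in the held-out samples only; (2) modality
perturbation — zeroing a whole modality *on the standardized scale*
(training-mean imputation on the raw scale) in the test matrix and
re-evaluating the unchanged model (a raw zero is an anatomically
impossible input; a `raw_zero` option exists); and (3) single-modality
refits on identical splits. Under the default generator, thickness
perturbation degrades MAE the most, the combined 77-feature model beats
every single-modality variant, ICV alone is worst, and the ventricle
structure coefficient is positive.

## Problem sizes and tolerances

The packaged verification runs use the full 6989-participant composition
for parameter-recovery (25 replicates) and interpretation-direction (10
replicates) checks, and outcome-level simulation (no imaging layer) at
6 sites × 40 for operating-characteristic checks (500 replicates for the
type-I error of the Dx Wald test, accepted at 5% ± 2.5 points). Ridge
fits are verified against a normal-equations oracle at 1e-8; single-site
mixed fits against OLS at 1e-6 relative; BH-FDR against a hand-computed
oracle. Numerical tie-breaks: zero-variance features are fit errors (the
scaler is undefined); a constant outcome yields a zero-variance result;
correlations of constant vectors are reported as NaN and flagged rather
than raised.
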