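# Methods

## The analysis pipeline

The package reproduces, end to end, the statistical treatment applied to
multi-center longitudinal plasma N-glycome data from a dietary-intervention
cohort (eight European centers; blood drawn at baseline T1, after an 8-week
low-calorie diet T2, and after 6 months of weight-maintenance diets T3).

1. **Total-area normalization.** Each sample's 39 UHPLC glycan-peak areas
   are divided by the chromatogram total and multiplied by 100, closing
   every row to 100 %Area. This removes per-sample intensity differences
   and makes the data compositional.
2. **Log transform.** %Area values are natural-logged: the distributions
   are right-skewed and plate effects act multiplicatively. Zero areas
   (absent in clean chromatograms, possible in sparse inputs) are governed
   by a policy: `error` or `halfmin` (replace by half the peak's smallest
   positive value; the default, with the imputed count logged).
3. **Plate batch correction.** Parametric empirical-Bayes location–scale
   adjustment (the ComBat model) with plate as the batch variable and an
   intercept-only mean model. Per peak g and plate b the location shift
   γ_bg and the variance ratio δ²_bg are estimated on standardized data,
   shrunk across the 39 peaks toward a normal / inverse-gamma prior whose
   hyperparameters come from method of moments, iterated to a fixed point
   (relative change < 1e-4, ≤ 100 iterations, both configurable), and
   removed. A location-only variant (`mean_only`) is available because the
   wording of the source analysis ("estimated batch effects were
   subtracted") does not identify which variant was used; location–scale
   is the default, being the canonical form. A single plate yields the
   identity adjustment; a plate with one sample is an error (scale not
   estimable); zero-variance peaks are left uncorrected with a warning.
   Technical replicates and plasma standards participate in batch
   estimation — that is what they are on the plate for — and are dropped
   before modeling.
4. **Back-transform.** Corrected log values are exponentiated and rows
   re-closed to 100 so derived traits remain interpretable as percentages.
5. **Derived traits.** Sixteen weighted sums over GP1–GP39 (weights 0.5
   or 1; peak GP12 contains co-eluting structures and is split equally
   between two families). Three families partition the glycome exactly:
   LB+HB+HM = 100, ΣG0..G4+HM = 100, ΣS0..S4+HM = 100. The table ships as
   YAML; `validate_trait_partitions` checks the closures for any
   user-supplied table before computation.
6. **Rank-inverse-normal transform.** Each trait is mapped to
   Φ⁻¹((r−0.5)/n) of its average ranks. Ties share a value (reproducible,
   unlike random tie-breaking); Blom's (r−3/8)/(n+1/4) is available via
   parameters. The transform is applied **within center**, pooling that
   center's samples across all time points, so a center's longitudinal
   model sees one coherent standard-normal scale; a global scope is a
   config option (the source analysis does not state which was used).
7. **Per-center mixed models.** For each trait, center, and period
   (T1→T2, T2→T3 as two separate paired analyses), a random-intercept
   model y = β0 + β_time·time + β_age·age + β_sex·sex + β_bmi·bmi +
   u_subject + ε is fitted by REML (statsmodels MixedLM; ML via config),
   with time coded 0/1 within the period. Baseline covariates are
   carried to all time points so BMI does not absorb the weight-change
   signal. Constant covariates are dropped with a warning; non-converged
   fits are excluded from pooling.
8. **Random-effects meta-analysis.** Center coefficients are pooled with
   inverse-variance weights 1/(se²+τ²); τ² is the maximum-likelihood
   estimate obtained by maximizing the profile marginal likelihood over
   τ² ∈ [0, ∞) (bounded scalar optimization, boundary checked). The
   pooled SE is (Σw)^(−1/2); p-values and 95% CIs use the normal
   approximation (no small-k t adjustment), matching the named method's
   defaults.
9. **FDR control.** Benjamini–Hochberg step-up applied **jointly** to all
   32 tests (16 traits × 2 periods). Recomputing the published tables
   confirms this pool: the 4th-ranked adjusted value and the shared
   0.51133 for two traits in period 2 only arise when both periods'
   p-values are adjusted together.
10. **Diet-arm contrast.** For randomized subjects the period-2 model is
    extended with arm main effects and arm × time interactions (control
    arm as reference); interaction coefficients are meta-analyzed per
    (trait, arm) and BH-adjusted jointly over all contrasts. Centers
    missing an arm contribute nothing to that arm.

A published-table replay (`replay_printed_tables`) recomputes steps 9–10's
arithmetic from the 32 published raw p-values shipped with the package and
compares to the published adjusted values row by row. Because the raw
inputs are printed at 3 significant digits, recomputed adjusted values can
differ from the printed ones by up to half a unit in the third digit;
the comparison allows exactly that input-rounding propagation (0.5%
relative) and nothing more. The replay reports 11 significant traits for
T1–T2 and 7 for T2–T3 at adjusted p < 0.05; note the source text says
"six" for the second period in one place while its own table and caption
give seven (the HM adjusted p of 0.04994 sits just under 0.05) — the
package reports the computed count.

## The synthetic cohort generator

Real per-subject data for this design are confidential, so the generator
produces cohorts with the statistical structure the pipeline assumes, plus
a truth record for recovery tests.

**Latent model.** Per subject i, peak g, time t the natural-log abundance
is log b_g + u_ig + (covariate loadings · covariates_i) + κ_g(t), with
per-(subject, peak) intercepts u_ig ~ N(0, σ_u²). A scalar per-subject
intercept would cancel under total-area normalization, so the random
intercept the downstream model absorbs must live at the peak level.
Measured log areas add a per-sample intensity factor (removed by
normalization), the plate's per-peak location effect γ_bg ~ N(0, σ_loc²),
and residual noise with sd σ_e·d_b, log d_b ~ N(0, σ_scale²). Replicates
re-measure a source sample's latent state with fresh noise on their own
plate; four plasma standards per plate share one latent profile.

**Defaults** (log scale unless stated): σ_u = 0.25, σ_e = 0.10,
σ_loc = 0.10, σ_scale = 0.20, intensity sd 0.30; age ~ N(41, 6.5²) y,
BMI ~ N(34, 4²) kg/m², sex Bernoulli(0.5), with small per-peak loadings
(sd 0.002/y, 0.02, 0.003 per kg/m²); 8 centers × 80 subjects; dropout
165/938 ≈ 17.6% after T2 (non-informative); 26 plates of ≤ 70 study
samples plus 5 within-plate and 5 cross-plate replicates and 4 standards.
The per-center subject count is not recoverable from the published totals
(1850 glycomes overall); 80 per center reproduces the study's scale on
26 plates. The baseline composition is a plausible right-skewed plasma
profile dominated by large biantennary sialylated peaks.

**Effect injection and calibration.** Trait effects are specified in
standardized units per (trait, period) and pushed down to member peaks in
proportion to trait weights. The latent multiplicative shift κ is solved
by a damped Newton iteration against a Monte-Carlo emulation of the
pipeline's own measurement: pseudo-centers of the configured size, each
subject contributing correlated samples at the pooled, rank-normalized
center scale (common random numbers make the solve deterministic under the
seed). This matters for two reasons. First, pooled rank-INT of clustered
longitudinal data at a finite center size yields a slightly larger group
difference than the independent-draws population value for skewed traits
(a subject's own nearby samples widen the rank distance between their time
points) — an intrinsic property of the rank-based method, so the estimand
is calibrated, not the unreachable population value. Second, traits are
compositionally coupled (raising one family's peaks depresses every other
share, and HB ≡ G3+G4 exactly), so simultaneous targets are solved
jointly; the exact closure dependence makes some target combinations
rank-deficient, which the damped step resolves as a least-squares
compromise. The truth record stores the nominal targets and the realized
effect of **every** trait (active and passive) on the measurement scale,
alongside all latent parameters.

**What the generator does not emulate:** chromatographic drift and
plate-position effects, informative dropout, non-lognormal abundance
distributions, center-level heterogeneity in effect sizes (τ² truth is 0),
and real between-peak correlation structure beyond compositional closure.
Passing calibration tests therefore demonstrate the pipeline's correctness
under its own assumptions, not robustness to violations of them.

## Numerical choices

- Meta-analysis τ²: bounded scalar maximization of the profile likelihood
  with the τ² = 0 boundary compared explicitly; tests pin it to a 1e-6
  grid search.
- Mixed models: lbfgs first, falling back to the default optimizer chain
  when the group variance lands on the zero boundary (where lbfgs can hit
  a singular matrix).
- CIs stored in result rows are validated against effect ± 1.959964·se at
  1e-9; result CSVs carry 12 significant digits (round-trip exact at that
  precision); the publication-style renderer prints 5 decimals for effects/SEs
  and 3-significant-digit scientific notation for small p-values.
- Problem sizes in tests and the acceptance script (3–4 centers, 40–60
  subjects/center, 10–12 replicate cohorts) are scaled-down study designs
  chosen to make Monte-Carlo checks sharp at desk scale; the generator's
  defaults reproduce the full design.

## Known limitations

- The acceptance surface for the published effect sizes is the
  multiple-testing arithmetic and calibration on synthetic cohorts: the
  per-subject data behind the published center effects are confidential,
  so those numbers cannot be recomputed from raw inputs.
- The diet-arm contrast needs every arm present in a center; small
  synthetic cohorts can drop contrasts (logged, never silently wrong).
- ComBat here is the parametric location–scale form with intercept-only
  mean model; nonparametric and reference-batch variants, and covariates
  in the batch mean model, are out of scope.
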