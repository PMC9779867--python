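# glycodiet

Multi-center longitudinal analysis of UHPLC plasma N-glycome derived
traits — the statistical pipeline behind dietary-intervention glycomics
studies, built for analysts who have a sample × glycan-peak area table and
a study design and want pooled, FDR-controlled estimates of how glycome
composition changes over intervention periods.

Plasma N-glycans are quantified as 39 chromatographic peaks (GP1–GP39),
each expressed as a percentage of the total integrated area (%Area).
Sixteen derived traits summarize them by shared structure — branching
(LB, HB), galactosylation (G0–G4), sialylation (S0–S4), bisecting GlcNAc
(B), antennary/core fucose (AF, CF) and high-mannose (HM) — as weighted
sums with weights in {0.5, 1} (peak GP12 splits between two families).
Three families close exactly: LB+HB+HM = ΣG+HM = ΣS+HM = 100.

The pipeline: total-area normalization → natural log → empirical-Bayes
plate batch correction (the ComBat model, plate as batch) → derived
traits → per-center rank-inverse-normal transform → per-center
random-intercept mixed models

  y = β₀ + β_time·time + β_age·age + β_sex·sex + β_bmi·bmi + u_subject + ε

(REML; time coded 0/1 within each period) → random-effects meta-analysis
across centers with maximum-likelihood τ² (pooled effect μ̂ = Σwθ/Σw,
w = 1/(se²+τ̂²)) → Benjamini–Hochberg step-up jointly over all 16 traits ×
2 periods, plus a diet-arm × time interaction contrast for the
weight-maintenance period.

Because real cohorts of this design are confidential, the package includes
a first-class synthetic-cohort generator: 8 centers, 3 time points with
dropout, block-randomized plates carrying technical replicates and plasma
standards, multiplicative plate effects, compositional log-normal peaks,
subject-level random intercepts, covariates, and injectable trait effects
calibrated so the nominal standardized effect equals what the pipeline
measures. Every latent parameter lands in a truth record for recovery
tests. See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a 4-center cohort with three injected effects (AF +0.35 and
LB +0.30 over the diet period, G3 −0.25 over the maintenance period) and
run the full pipeline:

```python
import glycodiet as gd

cfg = gd.SimulationConfig(
    n_centers=4, subjects_per_center=50, n_plates=9, samples_per_plate=70,
    trait_time_effects={("AF", "T1T2"): 0.35, ("LB", "T1T2"): 0.30,
                        ("G3", "T2T3"): -0.25},
    seed=42,
)
result = gd.run_pipeline(gd.PipelineConfig(simulation=cfg, seed=42))
```

The top of `result.meta_results` (publication-style formatting):

```
trait_code period   effect      se  p_value p_adjusted
        AF   T1T2  0.38806 0.04776 4.48e-16   1.43e-14
        HB   T1T2 -0.28948 0.04675 5.96e-10   9.53e-09
        G3   T2T3 -0.27767 0.04536 9.28e-10   9.90e-09
        LB   T1T2  0.30714 0.05120 1.99e-09   1.59e-08
        G3   T1T2 -0.22946 0.04533 4.16e-07   2.23e-06
```

Each `effect` is the change over the period in SD units of the
rank-normalized trait, pooled over centers; `p_adjusted` is the joint BH
value. The injected AF/LB/G3 effects are recovered at their calibrated
truth (0.353, 0.295, −0.249 in `result.truth.realized_effects`), and the
compositionally coupled traits respond as they must — pushing
low-branching glycans up drags the high-branching family (HB, here
−0.289) down without any HB effect being injected.

The same run from a shell:

```bash
glycodiet simulate --seed 42 --out sim/           # peaks.csv, annotation.csv, truth.json
glycodiet run --peaks sim/peaks.csv --annot sim/annotation.csv --out results/
glycodiet replay-tables                           # published-table arithmetic check
```

`glycodiet run` writes `meta_results.csv`, `center_effects.csv`,
`forest_data.csv` (per-center + pooled effects for forest plots),
`trait_deltas.csv` (mean trait levels normalized to baseline = 100),
`diet_contrasts.csv`, and a `run_log.json` with stage checksums; two runs
with the same seed are byte-identical.

`glycodiet replay-tables` recomputes the joint BH adjustment from the 32
published raw p-values shipped with the package and verifies every
published adjusted value at its printed precision, reporting 11
significant traits for the diet period and 7 for the maintenance period.

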