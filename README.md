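# oxyphen

Oxytocin, leptin and disordered eating across metabolic obesity
phenotypes: a reproducible biostatistics pipeline exercised on a
calibrated synthetic cohort.

## The scientific problem

Obesity is heterogeneous: some normal-weight adults are metabolically
unhealthy while some obese adults are not. Classifying adults into four
metabolic obesity phenotypes — MHNW (metabolically healthy normal
weight), MUNW, MUOW and MUO (metabolically unhealthy obese) — from BMI,
insulin resistance (HOMA-IR = insulin × glucose / 22.5) and hepatic
steatosis risk (HSI = 8·ALT/AST + BMI + 2·[female] + 2·[diabetes])
exposes gradients that BMI alone hides. Plasma oxytocin, an
appetite-regulating hypothalamic neuropeptide, falls across worsening
phenotypes while leptin, an adiposity signal, rises; both track
disordered-eating severity measured by the EDE-Q, DEBQ and EBA-O
questionnaires, with a binary outcome defined as global EDE-Q ≥ 2.5.

The pipeline implements the full analysis chain around those measures:

- **Group statistics** — Shapiro–Wilk normality gating, tie-corrected
  Kruskal–Wallis H, Dunn's post hoc z-tests with Bonferroni or
  Benjamini–Hochberg adjustment, pooled-SD Cohen's d, Spearman
  correlation matrices, cutoff prevalence tables.
- **Association models** — OLS with HC3 sandwich standard errors,
  backward elimination at p < 0.10, VIF diagnostics, standardized β,
  and a PCA replacement of collinear questionnaire subscales.
- **Dose–response** — logistic regression on a restricted cubic spline
  basis of oxytocin (k = 4 knots at quantiles 0.05/0.35/0.65/0.95),
  with pointwise percentile-bootstrap confidence bands.
- **Prediction** — leakage-free nested 5×5 stratified cross-validation
  of (A) the oxytocin-only spline model and (B) an elastic-net logistic
  model (oxytocin spline + leptin, BMI, WC, HSI, VAI and a PCA-derived
  EDE-Q component), every preprocessing constant learned inside the
  training fold; pooled out-of-fold (OOF) predictions feed the
  Mann–Whitney AUC, Brier score, logistic recalibration
  intercept/slope, Youden-optimal operating point with bootstrap CIs,
  and a paired-bootstrap ΔAUC test.
- **Cutoff inversion** — the Youden probability threshold p* is mapped
  back to an oxytocin concentration by finding where the fitted
  dose–response curve falls through p*, with a refit-and-invert
  bootstrap CI.
- **Decision curves** — net benefit NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)
  against treat-all and treat-none.

Because participant-level data of this kind are typically available
only on request, the package ships a seeded synthetic cohort generator
whose frozen defaults reproduce the cohort's published summary
structure: a 4-component phenotype mixture (18/12/13/56 of 99), 76.8%
female, right-skewed hormones with opposite phenotype gradients,
Spearman ≈ −0.73 between oxytocin and global EDE-Q, ≈ +0.92 for leptin,
and outcome prevalence ≈ 0.64. All statistical machinery is tested
against independent oracles; the generator provides known-truth
scenarios (e.g. a monotone risk curve crossing p* = 0.69 exactly at
90 pg/mL) for recovery testing.

## Worked example

```sh
oxyphen simulate --seed 20250320 --n 99 --outdir results/run
oxyphen analyze  --cohort results/run/cohort.csv --outdir results/run
oxyphen predict  --cohort results/run/cohort.csv --outdir results/run --seed 20250320
oxyphen report   --outdir results/run
```

or equivalently run the numbered drivers `analysis/01…07`. On the
default seed the pipeline prints:

```
oxytocin_only: OOF AUC 0.930 (95% CI 0.872–0.975), Brier 0.097, p* 0.566,
               sens 0.92, spec 0.86, calibration slope 0.87 / intercept -0.03
combined:      OOF AUC 0.985 (95% CI 0.957–1.000), Brier 0.112, p* 0.629,
               sens 0.98, spec 0.95
paired ΔAUC (combined − oxytocin-only): +0.055 (95% CI +0.014–+0.102; p = 0.004)
p* = 0.566 inverts to oxytocin ≈ 62.6 pg/mL (95% CI 47.8–81.9)
```

Reading: on this synthetic cohort the oxytocin-only spline model
discriminates well out-of-fold, the multivariable model adds a small
but significant increment (the paired bootstrap CI for ΔAUC excludes
0), and the optimal operating probability corresponds to an oxytocin
concentration below which predicted risk of clinically elevated
disordered eating exceeds the threshold. Exact numbers are properties
of the synthetic cohort, not of any real population.

## Layout

```
src/oxyphen/        library (generator, indices, statistics, spline
                    logistic, elastic net, nested CV, evaluation, DCA, CLI)
analysis/           numbered narrative drivers writing results/analysis/
tests/              pytest suite incl. end-to-end acceptance properties
scripts/acceptance.py
docs/methods.md     modelling assumptions, parameter choices, limitations
```
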