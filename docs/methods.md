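# Methods notes

This note records the modelling assumptions, default parameters and
numerical choices behind the package, and what the synthetic-data tests
do and do not demonstrate.

## Synthetic cohort generator

The generator emulates a cross-sectional adult cohort (n = 99 by
default) in which disordered-eating severity co-varies with an
adiposity hormone (leptin, positively) and a neuropeptide (oxytocin,
negatively) across four metabolic obesity phenotypes.

**Structure.** A phenotype label is drawn first from a multinomial with
probabilities 18/99, 12/99, 13/99, 56/99 (MHNW, MUNW, MUOW, MUO); all
biometrics are generated conditional on it. Hormones and right-skewed
labs (insulin, transaminases, GGT, triglycerides, …) are log-normal
with phenotype-specific locations — log-oxytocin decreasing and
log-leptin increasing from MHNW to MUO — and a within-phenotype
correlation of −0.20 between the two hormone logs. BMI is a truncated
normal inside each phenotype's BMI class (normal 18.5–24.9, overweight
25–29.9, obese ≥ 30), which keeps every draw inside the eligibility
rule BMI ≥ 18.5 kg/m². Sex is female with probability 0.768; age is a
truncated normal 38.9 ± 10.4 on 18–65. Leptin is generated and
reported in ng/mL.

**Severity and questionnaires.** A latent severity is
`1.0·z(log leptin) − 0.16·z(log oxytocin) + ε`, ε ~ N(0, 0.42²), and
the global EDE-Q score is `6·σ(0.60·(severity − 0.2565))`, a logistic
squashing onto the 0–6 instrument scale. The twelve subscales are the
global score plus independent N(0, 0.5²) noise, re-clipped to 0–6
(EDE-Q, EBA-O) or mapped to 1–5 (DEBQ); this one-factor construction
reproduces the strong subscale intercorrelation with minimal
parameters. The binary outcome is global EDE-Q ≥ 2.5.

**Calibration.** The severity coefficients, noise SD and squashing
constants were tuned once against a 400 000-participant simulation so
that the default cohort hits its target summary statistics — Spearman
(oxytocin, global) ≈ −0.73, Spearman(leptin, global) ≈ +0.92, outcome
prevalence ≈ 0.64 — and then frozen. Because the global score is a
monotone transform of severity, the rank correlations depend only on
the severity construction, and the squashing center is the severity
quantile that fixes the prevalence. Measured values at n = 5000:
−0.744, +0.917, 0.640.

**What the generator does not emulate:** assay noise, menstrual-phase
or medication effects, missing data patterns, or the exact marginal
distributions of every lab. Passing tests therefore demonstrate that
the statistical machinery is correct and leakage-free under a
plausible data-generating process, not that any real cohort would
yield the same estimates.

**Known-truth scenarios.** For recovery testing the questionnaire
outcome can be replaced by a Bernoulli draw from a specified
probability law of oxytocin — flat, monotone logistic, or U-shaped in
the logit. The monotone default passes through probability 0.69 at
90 pg/mL with logit slope −0.04 per pg/mL, matching the gross shape of
a risk curve that falls from ~0.95 at very low oxytocin to ~0.3 above
100 pg/mL. Generated oxytocin spans well beyond [10, 200] pg/mL, so
the 90 pg/mL crossing is interior to the support.

## Metabolic indices and phenotyping

HOMA-IR, HSI and the sex-specific VAI use their standard reference
equations. The atherogenic index is (TC − HDL)/HDL, the most common
definition at the magnitude reported for such cohorts; it is a
documented assumption. Phenotyping: metabolically unhealthy ⇔
HOMA-IR ≥ 2.5 or HSI ≥ 36 (the NAFLD-risk bound), independent of BMI;
the BMI class then selects MHNW/MUNW/MUOW/MUO. Metabolically healthy
overweight/obese individuals fall outside the four-group scheme and
are labelled `unclassified` and excluded from four-group contrasts.
These cutoffs are explicit substitutes for unavailable study
definitions, chosen from conventional adult bounds.

## Group statistics

Average ranks for ties throughout; Kruskal–Wallis uses the
tie-corrected H with a χ²(k−1) reference, and Dunn's z uses the
matching tie term. All-identical samples are degenerate (H = 0,
p = 1), not errors. Dunn adjustment defaults to Bonferroni, with
Benjamini–Hochberg available; across-variable Kruskal–Wallis p-values
additionally receive a BH q, and the family size is the number of
variables passed (recorded in the output). Missing values are handled
listwise within each test and pairwise-complete for Spearman
correlations; a constant column yields an undefined (NaN) correlation
rather than an error.

## Robust regression

HC3 sandwich covariance with t(n−p) inference — the small-sample
convention. Backward elimination refits after dropping the single
worst predictor with p strictly above 0.10, so a predictor sitting
exactly at the threshold is retained; the intercept is never dropped,
and an all-noise candidate set legitimately collapses to the
intercept-only model. Residual diagnostics are reported (fitted values
and residuals are kept on the fit object; Shapiro–Wilk can be applied
to residuals) but trigger no automatic remediation. PCA components are
computed on internally standardized variables and sign-oriented so
each score correlates non-negatively with the mean of its inputs,
making the loadings reproducible across platforms.

## Spline logistic dose–response

Restricted cubic basis with k = 4 knots (configurable 3–5) at the
standard quantile probabilities; the basis is scaled by (t_k − t_1)²
for conditioning, which rescales coefficients but not fitted
probabilities. Fitting is Newton–Raphson with step halving, converging
on a score infinity-norm below 1e-8; separation is flagged when any
standardized coefficient exceeds 15 or the fit classifies perfectly
without score convergence. Bootstrap bands are pointwise 2.5/97.5
percentiles over case resamples with knots re-placed per resample;
failed replicates are dropped and counted. At finite B a percentile
band can sit on the wrong side of the point fit at isolated grid
points, so bands are clipped to enclose it. The default evaluation
grid is 200 points between the 0.5th and 99.5th percentile of the
data; the extreme 0.5% tails are excluded because a handful of extreme
draws of a heavy-tailed biomarker would otherwise dominate the grid
resolution.

## Elastic net and nested cross-validation

The penalized logistic objective is −(1/n)·loglik + λ(α‖β‖₁ +
(1−α)/2‖β‖₂²) with an unpenalized intercept on standardized
predictors, solved by IRLS with cyclic coordinate descent and verified
against the KKT stationarity conditions (residual < 1e-8 at
convergence); λ paths are warm-started from λ_max (the smallest λ
zeroing all penalized coefficients) down to λ_max·1e-4 over 50
log-spaced values, α ∈ {0.1, …, 1.0}.

Folds are stratified 5×5; every preprocessing constant — imputation
medians, spline knots, PCA mean/scale/loading, centering and scaling —
is learned on the outer-train split only, and applying a fitted fold
to any data uses only those stored constants. This is asserted
bitwise: corrupting a fold's held-out rows changes nothing the fold
learned. Hyperparameters maximize mean inner-fold AUC (discrimination
is the headline selection surface; miscalibration of the combined
model is measured downstream rather than prevented), and the model is
refit on the full outer-train split at the selected pair. The
EDE-Q-subscale PCA predictor of an EDE-Q-derived outcome is circular
by construction; it is retained by default to mirror the published
model, and `combined_spec(drop_edeq_component=True)` removes it.

OOF probabilities are pooled across folds before any ROC computation.

## Evaluation

AUC is the Mann–Whitney estimator (exactly the all-pairs concordance
with half-credit ties). The Youden threshold scans the observed
prediction values, breaking ties toward the higher threshold (higher
specificity); bootstrap CIs for sensitivity and specificity repeat the
whole scan inside each replicate. The paired ΔAUC test recomputes both
AUCs on shared case resamples; its two-sided p uses a +1 continuity
correction in numerator and denominator, so the self-comparison null
gives exactly p = 1. Calibration slope is the coefficient of
logit(p̂) in a logistic refit, and the intercept comes from a refit
with logit(p̂) as a fixed offset; predictions are clipped at 1e-6.
Cutoff inversion finds sign changes of p̂(x) − p* on the evaluation
grid with linear interpolation, reports every crossing, and selects
the smallest value where the curve falls from above to below p* (low
biomarker = high risk); a curve that never falls through p* yields an
explicitly flagged empty mapping. All bootstrap intervals are seeded
percentile intervals (B = 2000 by default, smaller in tests).

## Decision curves

Net benefit on a 0.05–0.95 threshold grid in steps of 0.01, which
contains the clinically discussed 0.10–0.80 range, with treat-all and
treat-none references and the cohort prevalence marked.

## Problem sizes used in the test suite

Simulation-backed checks run at the smallest sizes that make their
assertions sharp: calibration envelopes at n = 5000, recovery of the
90 pg/mL known-truth cutoff at n = 1000 with B = 200 over 100 seeds
(errors measured in units of each cohort's own grid resolution),
permutation nulls as 50 shuffles of the 99-participant cohort, and
elastic-net/AUC/DCA identities on a few hundred observations. These
sizes are the package's documented study conditions for its own
regression tests.

## Known limitations

- The subscale model is single-factor; real questionnaires show
  subscale-specific structure the generator flattens.
- Phenotype cutoffs and the atherogenic-index formula are conventional
  substitutes, not study-verified definitions.
- The cutoff-inversion CI ignores uncertainty in p* itself when a
  fixed threshold is supplied.
- Percentile (not BCa) bootstrap everywhere; with B in the low
  hundreds the interval endpoints are noticeably seed-dependent.
- No comparator ensemble models (random forest, boosting); the module
  boundary where they would plug in is `nested_cv.ModelSpec`.
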