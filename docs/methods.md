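# Methods

This note documents the models, the simulator, the numerical choices and
the limits of what the test suite demonstrates.

## The analysis in brief

One week of wrist acceleration per participant is summarized as 24 hourly
means over the daily cycle. The analysis asks whether these diurnal
profiles, together with month of wear, sex, age and weight, separate
(1) healthy people from anyone with a knee-osteoarthritis (KOA) diagnosis
at any time, (2) prodromal from already diagnosed KOA, and (3) healthy
people from those diagnosed within the next five years. "Prodromal" means
undiagnosed at the wear week with a qualifying ICD-10 M17.x diagnosis
recorded within the following ten years.

## Cohort construction

Eligibility: complete, finite hourly profiles; no hourly value strictly
above 1000 (an anomaly threshold in the stored acceleration units); BMI
≥ 29 (the restriction that controls adiposity confounding — below this
value BMI, not disease, dominates activity differences). Boundary
handling is deliberate: a value exactly 1000 and a BMI exactly 29.0 are
both kept; a diagnosis on the wear day (offset 0) counts as diagnosed.
Diagnoses more than ten years after wear are a fourth, explicitly flagged
category: they count as cases in scenario 1 (a KOA diagnosis "at any
time") but are excluded from the prodromal class in scenarios 2–3 and
noted in the provenance log.

Scenarios 1 and 3 are balanced 1:1 by undersampling controls with weights
proportional to the case/control density ratio over (sex stratum, 5-year
age bin, 2-unit BMI bin). Sex is exact; age and BMI are binned because the
density ratio must be estimated from finite samples and these widths trade
bias against variance at cohort sizes of a few hundred to a few thousand.
When too few controls fall in case-occupied strata the weights receive a
small floor over same-sex strata (logged), preferring a slightly worse
match over a hard failure. Matching quality is reported as standardized
mean differences before and after. Height is not a matching variable.
Scenario 2 keeps every eligible participant and is therefore mildly
imbalanced, as in the source design.

## The classifier

Architecture (all dimensions configurable, defaults in parentheses):

- profile (24,) → conv1d 1→16 (kernel 3, stride 1, zero same-padding) →
  batch norm → ReLU → conv1d 16→32 → batch norm → ReLU → global average
  pooling over the 24 positions → 32 features;
- month → embedding (4), sex → embedding (2);
- (age, weight) → linear → ReLU (8);
- concatenation (46) → linear → ReLU (32) → linear → softmax (2).

Training: cross-entropy, Adam at learning rate 10⁻³ with canonical
moments (0.9, 0.999), batch size 64, exactly 30 epochs with per-epoch
shuffling, no early stopping, no dropout, no weight decay. Weights use
uniform ±1/√fan-in initialization; embeddings standard normal. The entire
network and its reverse-mode gradients are written in numpy float64; a
finite-difference check in the test suite verifies every layer's
gradients through the full composition, and the default configuration has
3374 parameters, matching a closed-form layer-by-layer count.

Inference freezes batch-norm statistics at their running averages
(momentum 0.1), so predictions are batch-size independent; a test checks
batch-vs-single-record equivalence to 1e−12.

**Input standardization.** Age and weight are z-scored per covariate with
training-fold statistics. The profile is standardized with a *single
global* mean and SD over all hours of the training fold, not per hour.
This is a considered choice: the encoder pools feature maps uniformly
over time and normalizes per channel over batch and time, so it has no
positional information — the only way it can locate the informative
daytime hours is through the diurnal level differences themselves, which
per-hour centring would erase (every hour would become mean-zero and
exchangeable). Empirically the global scheme raises held-out AUC by
roughly 0.03 on calibrated cohorts and leaves null behaviour unchanged.

**A structural limit worth knowing.** Because pooling is uniform and
convolution is translation-invariant, this architecture cannot apply
hour-specific weights; it selects daytime hours only implicitly, through
their higher activity levels relative to the hourly noise. On cohorts
whose separability is defined through an hours-9–16 mean discriminant, it
therefore recovers somewhat less than a positionally informed linear
model (cross-validated AUC ≈ 0.62 vs ≈ 0.65 for logistic regression at a
design AUC of 0.67, scenario-1 size ≈ 7400). This is a property of the
architecture, not a bug; the evaluation reports what the model achieves.

## Evaluation

Stratified five-fold cross-validation; per-fold accuracy, macro F1, macro
sensitivity (unweighted mean per-class recall; equal to accuracy for
exactly balanced classes), macro one-vs-rest AUC (for two classes the
rank-sum AUC with ties credited ½), and rows-are-truth confusion
matrices; mean ± SD over folds uses the k−1 denominator. Significance:
Pearson chi-squared of independence on the best fold's confusion matrix
(best = highest accuracy; no Yates correction — counts are large and the
plain test of independence is the cited procedure), a one-sample
proportion z-test of the pooled out-of-fold accuracy against 0.5 with
null-variance denominator √(¼/n), and a one-sample t-test of the five
fold accuracies against 0.5. All three are reported; none is a substitute
for another.

## The synthetic-cohort generator

The generator defines the study conditions under which everything is
tested. Defaults (all configurable in `SyntheticConfig`):

- Diurnal template: nocturnal plateau 10 mg for hours 0–5, linear rise to
  a 40 mg peak at 10:00, linear decline towards night level by midnight.
  The milli-gravity-like scale is arbitrary but internally consistent;
  what matters is the ratio of effect to noise.
- Seasonality: multiplicative 1 + a·cos(2π(month − 7)/12) with a = 0.2 —
  July maximal, January minimal, matching Northern-hemisphere wear.
- Hourly noise: independent Gaussian, SD 15 mg, clipped at zero
  (acceleration magnitudes cannot be negative). Independence across hours
  is the simplest model consistent with hourly aggregates of a noisy
  magnitude signal.
- Demographics: age 65.5 ± 7.5 y (clipped 40–85), 47% male, BMI 31 ± 3
  kg/m² (so roughly a quarter of participants fall below the BMI ≥ 29
  filter and the eligible cohort mirrors the restricted real one); weight
  is derived from BMI and a sex-specific height draw (175.6 ± 6.8 cm men,
  162.1 ± 6.3 cm women, UK survey values).
- BMI–activity coupling: daytime hours lose 0.6 mg per BMI unit above 25,
  so the BMI filter and the matching are exercised against a real
  activity gradient. Setting the slope to zero disables it.
- Case effect: hours 9–16 multiplied by (1 − δ) before noise, localizing
  the group gap to the active day, with δ = 0.10 by default. Cases are
  12% of participants; 57% are prediagnosed (offset uniform on (−10, 0))
  and 43% prodromal (offset uniform on (0, 10]), mirroring the 2081:1596
  split of the real cohort. Controls carry no qualifying code; 5% of
  everyone gets an unrelated distractor code to exercise prefix matching.

**Calibration.** `calibrate_attenuation` inverts the closed form
AUC = Φ(d/√2) with d = δ·μ_day/σ_day, where μ_day is the seasonal-neutral
template mean over hours 9–16 and σ_day = noise_sd/√8 is the SD of the
daytime mean induced by the hourly noise. The form is exact when
seasonality and BMI coupling are off; with them on, month and weight are
observed covariates that a conditioning model can remove, so the
calibrated δ still describes the separability available to the
multi-modal classifier (the unconditional daytime-mean AUC is then
somewhat lower). A simulation test checks the closed form within ±0.02 on
20 000 case-control pairs under its assumptions.

**What the generator does not emulate:** within-week wear variation and
non-wear, autocorrelated hourly noise, activity-type composition, reverse
causation near diagnosis, or coding delay heterogeneity. Passing tests
therefore demonstrate that the pipeline recovers the signal structure it
assumes, at the stated effect sizes — not that the real-data effect sizes
are correct.

## Problem sizes and numerical choices

Tests use cohorts of 700–6000 participants for unit and property checks,
20 replicates of 2000 for null calibration, and one 41 000-participant
cohort (scenario-1 dataset ≈ 3700 per class, the published scale) for
signal recovery; these sizes give Monte-Carlo error comfortably inside
the asserted tolerances while keeping the full suite around five minutes
on one CPU. Determinism is end to end: a single run seed derives
per-stage seeds through `numpy.random.SeedSequence`, and identical
configurations reproduce cohorts, splits and metric files byte for byte.
Degenerate inputs fail loudly: empty scenario classes, single-class
training sets, classes smaller than k, zero chi-squared marginals and
infeasible calibration targets all raise typed errors rather than
returning silently wrong numbers.

## Known limitations

- The conv+GAP encoder's positional blindness (above) bounds achievable
  AUC below a linear model with hour-specific weights on this generator.
- Density-ratio matching with fixed bins can leave residual imbalance at
  small cohort sizes (a few hundred cases) and is logged, not enforced.
- The proportion z-test on pooled out-of-fold predictions treats pooled
  accuracy as binomial; fold dependence makes this mildly anti-
  conservative, which is why the fold-level t-test is reported alongside.
- Absolute acceleration units are arbitrary; only relative effects are
  meaningful.
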