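# actikoa

Digital-biomarker analysis of diurnal wrist-accelerometry profiles for knee
osteoarthritis (KOA) risk classification. The package implements, end to
end and without any external data download, a case-control pipeline in
which a week of wrist acceleration — reduced to 24 hourly means over the
daily cycle — is used to separate healthy people from those who carry, or
will later receive, a KOA diagnosis (ICD-10 M17.x). It is aimed at
researchers in actigraphy-based epidemiology who want a tested, fully
seeded reference implementation of this class of analysis, including a
synthetic-cohort generator with a controllable effect size so that every
stage is reproducible on a laptop.

## What it computes

**Cohorts.** Participants carry a 24-value profile *x*₀…*x*₂₃ (hourly mean
acceleration), month of wear, sex, age, weight and BMI. Eligibility
requires complete finite profiles, no hourly value > 1000, and BMI ≥ 29.
Disease status is labelled from the signed offset Δ (years) between the
wear week and the first qualifying diagnosis: Δ ≤ 0 diagnosed,
0 < Δ ≤ 10 prodromal (within 5 years when Δ ≤ 5), no code healthy. Three
scenarios are built: (1) healthy vs any KOA, (2) prodromal vs diagnosed,
(3) healthy vs prodromal-within-5-years; scenarios 1 and 3 are balanced
1:1 by weighted undersampling of controls with density-ratio weights over
sex strata, 5-year age bins and 2-unit BMI bins.

**Classifier.** A multi-modal network: the profile passes through two 1D
convolutions (16 and 32 filters, kernel 3, same padding), each with batch
normalization and ReLU, then global average pooling over the 24 positions;
month and sex enter through learned embeddings (dims 4 and 2); age and
weight through a dense ReLU projector (dim 8). The concatenated
representation feeds a two-layer head (hidden width 32) with softmax
output. Training is cross-entropy with Adam, learning rate 10⁻³, batch
size 64, exactly 30 epochs per fold. The network and its gradients are
implemented in numpy and verified against finite differences.

**Evaluation.** Stratified five-fold cross-validation reporting accuracy,
macro F1, macro sensitivity (mean per-class recall), macro one-vs-rest AUC
and confusion matrices, aggregated as mean ± SD across folds; a Pearson
chi-squared test of independence on the best fold's confusion matrix, a
one-sample proportion z-test of pooled accuracy against the 50% chance
baseline, z = (p̂ − ½)/√(¼/n), and a one-sample t-test of fold accuracies
against 0.5.

**Synthetic cohorts.** The generator draws profiles from a diurnal
template (nocturnal plateau, monotone rise to a 10:00 peak, decline to
midnight) scaled by a seasonal factor 1 + a·cos(2π(month − 7)/12), with
BMI-linked daytime decrement and truncated Gaussian hourly noise. Cases
have hours 9–16 attenuated by a factor (1 − δ); `calibrate_attenuation`
inverts AUC = Φ(δ·μ_day/(√2·σ_day)) to choose δ for a target daytime-mean
discriminant AUC.

## Worked example

`python examples/03_train_and_crossvalidate.py` calibrates the generator
to a design daytime-mean AUC of 0.67, builds the healthy-vs-KOA scenario
from a 12 000-participant synthetic cohort and cross-validates:

```
calibrated daytime attenuation for design AUC 0.67: delta = 0.0981
scenario 1 dataset: (1059, 1059) (healthy vs any KOA)
          accuracy: 0.561 ± 0.014
          f1_macro: 0.559 ± 0.012
 sensitivity_macro: 0.561 ± 0.014
         auc_macro: 0.580 ± 0.025
proportion z-test: z = 5.65, p = 1.61e-08
chi-squared (best fold): 11.72, p = 6.17e-04
fold t-test vs 0.5: p = 0.0006
```

The attenuation δ ≈ 0.10 means cases move about 10% less during 09:00–16:00
before noise. The cross-validated AUC of 0.58 at this cohort size, with
both significance tests far below 0.05, shows the classifier recovering a
modest but statistically solid signal — chance would give AUC 0.5 and
p-values near 1 (see `examples/01`–`04` for the other stages, and the
`actikoa` CLI for the same operations from a shell: `actikoa run-all
--seed 1 --out runs/demo`).

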