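"""Cross-validate the multi-modal classifier on a calibrated cohort.

Calibrates the generator's daytime attenuation so that the theoretical
daytime-mean discriminant sits at AUC 0.67 (the moderate-separability
operating point of the real analysis), then runs the stratified five-fold
evaluation and prints the metric summary with both significance tests.
Takes roughly a minute on one CPU.
"""

from actikoa import (
    ModelConfig,
    SyntheticConfig,
    build_scenario,
    calibrate_attenuation,
    cross_validate,
    filter_valid,
    generate_population,
)

base = SyntheticConfig(n_participants=12000, seed=3)
delta = calibrate_attenuation(0.67, base)
print(f"calibrated daytime attenuation for design AUC 0.67: delta = {delta:.4f}")

cfg = SyntheticConfig(n_participants=12000, daytime_attenuation=delta, seed=3)
kept, _ = filter_valid(generate_population(cfg))
dataset = build_scenario(kept, 1, seed=4)
print(f"scenario 1 dataset: {dataset.class_counts()} (healthy vs any KOA)")

summary = cross_validate(dataset, ModelConfig(), k=5, seed=5)
for metric in ("accuracy", "f1_macro", "sensitivity_macro", "auc_macro"):
    print(f"{metric:>18}: {summary.mean[metric]:.3f} ± {summary.sd[metric]:.3f}")
print(f"proportion z-test: z = {summary.proportion_z:.2f}, p = {summary.proportion_p:.2e}")
print(f"chi-squared (best fold): {summary.chi2_statistic:.2f}, p = {summary.chi2_p:.2e}")
print(f"fold t-test vs 0.5: p = {summary.fold_t_p:.4f}")
# A mean AUC clearly above 0.5 with tiny p-values reproduces the
# qualitative finding: a week of wrist actigraphy carries a modest but
# statistically solid disease signal.
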