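"""Worked metric examples on hand-checkable inputs.

Reconstructs fold metrics from published per-class recall rates, and
evaluates the two significance tests on small closed-form examples.
"""

from actikoa.evaluate import (
    chi_squared_confusion,
    compute_metrics,
    metrics_from_recalls,
    proportion_z_test,
)

# Best-model confusion rates for healthy-vs-KOA: 69% of class 0 and 58% of
# class 1 correct, 3677 participants per class.
fm = metrics_from_recalls(0.69, 0.58, 3677, 3677)
print("confusion:", fm.confusion)
print(f"macro sensitivity = {fm.sensitivity_macro:.3f} (mean of 0.69 and 0.58)")
print(f"accuracy          = {fm.accuracy:.3f} (equal to macro sensitivity when balanced)")

# AUC by exhaustive pair counting: 3 of 4 pairs concordant.
fm2 = compute_metrics([0, 0, 1, 1], [0, 0, 0, 1], [0.1, 0.4, 0.35, 0.8])
print(f"\ntoy AUC = {fm2.auc_macro:.2f} (3 concordant pairs of 4)")

stat, p = chi_squared_confusion([[69, 31], [42, 58]])
print(f"\nchi-squared on [[69,31],[42,58]]: statistic = {stat:.2f}, p = {p:.2e}")

z, p = proportion_z_test(0.75, 100)
print(f"proportion z for accuracy 0.75 at n=100: z = {z:.1f} (0.25 / 0.05), p = {p:.2e}")
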