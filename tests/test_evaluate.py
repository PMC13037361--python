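"""Metric suite, significance tests and the cross-validation loop.

Every metric is checked against an independent brute-force oracle: direct
confusion counting, per-class recall/F1 arithmetic, and exhaustive pair
enumeration for the AUC (ties credited one half).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actikoa.evaluate import (
    UndefinedTestError,
    chi_squared_confusion,
    compute_metrics,
    cross_validate,
    metrics_from_recalls,
    proportion_z_test,
    stratified_kfold,
)
from actikoa.cohort import build_scenario
from actikoa.model import ModelConfig


# ---------------------------------------------------------------- oracles
def oracle_confusion(y, yhat):
    c = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, yhat):
        c[t, p] += 1
    return c


def oracle_auc(y, scores):
    """Exhaustive pair enumeration; ties count one half."""
    pos = [s for t, s in zip(y, scores) if t == 1]
    neg = [s for t, s in zip(y, scores) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_metrics(y, yhat):
    c = oracle_confusion(y, yhat)
    recalls, f1s = [], []
    for k in (0, 1):
        tp = c[k, k]
        fn = c[k, 1 - k]
        fp = c[1 - k, k]
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        recalls.append(recall)
        f1s.append(f1)
    return {
        "accuracy": np.trace(c) / c.sum(),
        "sensitivity_macro": np.mean(recalls),
        "f1_macro": np.mean(f1s),
        "confusion": c,
    }


# ---------------------------------------------------------------- k-fold
class TestStratifiedKFold:
    def test_exact_divisibility(self):
        y = np.repeat([0, 1], 10)
        splits = stratified_kfold(y, k=5, seed=0)
        for _, ev in splits:
            assert [np.sum(y[ev] == c) for c in (0, 1)] == [2, 2]

    def test_partition_property(self):
        y = np.repeat([0, 1], [17, 23])
        splits = stratified_kfold(y, k=5, seed=3)
        all_eval = np.concatenate([ev for _, ev in splits])
        assert sorted(all_eval.tolist()) == list(range(40))
        for tr, ev in splits:
            assert not set(tr) & set(ev)

    def test_near_balance_with_uneven_classes(self):
        y = np.repeat([0, 1], [11, 9])
        splits = stratified_kfold(y, k=5, seed=1)
        for c in (0, 1):
            per_fold = [int(np.sum(y[ev] == c)) for _, ev in splits]
            assert max(per_fold) - min(per_fold) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.repeat([0, 1], [3, 50]), k=5, seed=0)

    def test_deterministic(self):
        y = np.repeat([0, 1], 30)
        a = stratified_kfold(y, k=5, seed=9)
        b = stratified_kfold(y, k=5, seed=9)
        for (ta, ea), (tb, eb) in zip(a, b):
            np.testing.assert_array_equal(ea, eb)


# ---------------------------------------------------------------- metrics
class TestComputeMetrics:
    def test_published_recall_rates_give_printed_macro_sensitivity(self):
        """Per-class recalls 0.69/0.58 with equal classes -> 0.635 for both
        macro sensitivity and accuracy."""
        fm = metrics_from_recalls(0.69, 0.58, 100, 100)
        assert fm.sensitivity_macro == pytest.approx(0.635)
        assert fm.accuracy == pytest.approx(0.635)

    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1])
        fm = compute_metrics(y, y, y.astype(float))
        assert fm.accuracy == fm.f1_macro == fm.sensitivity_macro == fm.auc_macro == 1.0
        assert fm.confusion_array()[0, 1] == fm.confusion_array()[1, 0] == 0

    def test_auc_by_pair_enumeration(self):
        y = [0, 0, 1, 1]
        scores = [0.1, 0.4, 0.35, 0.8]
        fm = compute_metrics(y, [0, 0, 0, 1], scores)
        assert fm.auc_macro == pytest.approx(0.75)
        assert fm.auc_macro == pytest.approx(oracle_auc(y, scores))

    def test_single_true_class_rejected(self):
        with pytest.raises(UndefinedTestError):
            compute_metrics([1, 1, 1], [1, 0, 1], [0.9, 0.2, 0.8])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0], [0.5, 0.5])

    @given(
        n=st.integers(4, 30),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=120, deadline=None)
    def test_metric_oracle_equivalence(self, n, seed):
        """All metrics agree with brute-force computation to 1e-12."""
        r = np.random.default_rng(seed)
        y = r.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        yhat = r.integers(0, 2, n)
        scores = np.round(r.random(n), 2)  # rounding forces occasional ties
        fm = compute_metrics(y, yhat, scores)
        expected = oracle_metrics(y, yhat)
        assert fm.accuracy == pytest.approx(expected["accuracy"], abs=1e-12)
        assert fm.sensitivity_macro == pytest.approx(expected["sensitivity_macro"], abs=1e-12)
        assert fm.f1_macro == pytest.approx(expected["f1_macro"], abs=1e-12)
        assert fm.auc_macro == pytest.approx(oracle_auc(y, scores), abs=1e-12)
        np.testing.assert_array_equal(fm.confusion_array(), expected["confusion"])

    def test_normalized_confusion_rows_sum_to_one(self):
        fm = compute_metrics([0, 0, 1, 1, 1], [0, 1, 1, 0, 1], [0.2, 0.6, 0.7, 0.3, 0.9])
        np.testing.assert_allclose(fm.normalized_confusion().sum(axis=1), 1.0)


# ---------------------------------------------------------------- tests of tests
class TestChiSquared:
    def test_hand_computed_example(self):
        """[[69,31],[42,58]] vs direct sum((O-E)^2/E) from the margins."""
        table = np.array([[69, 31], [42, 58]], dtype=float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        stat, p = chi_squared_confusion(table)
        assert stat == pytest.approx(by_hand)
        assert stat == pytest.approx(14.76, abs=0.01)
        assert p < 0.001

    def test_identical_rows_independent(self):
        stat, p = chi_squared_confusion([[50, 50], [50, 50]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_homogeneity_under_count_scaling(self):
        s1, _ = chi_squared_confusion([[69, 31], [42, 58]])
        s10, _ = chi_squared_confusion([[690, 310], [420, 580]])
        assert s10 == pytest.approx(10 * s1)

    def test_label_swap_invariance(self):
        t = np.array([[60, 40], [30, 70]])
        s1, _ = chi_squared_confusion(t)
        s2, _ = chi_squared_confusion(t[::-1, ::-1])
        assert s1 == pytest.approx(s2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(UndefinedTestError):
            chi_squared_confusion([[0, 0], [10, 20]])


class TestProportionZ:
    def test_chance_accuracy(self):
        z, p = proportion_z_test(0.5, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_example(self):
        z, p = proportion_z_test(0.75, 100)
        assert z == pytest.approx(5.0)
        assert p < 1e-6

    def test_table_scale_accuracy_is_significant(self):
        # pooled accuracy 0.635 at the n of the healthy-vs-KOA comparison
        _, p = proportion_z_test(0.635, 7354)
        assert p < 1e-4

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            proportion_z_test(1.2, 100)
        with pytest.raises(ValueError):
            proportion_z_test(0.5, 0)


# ---------------------------------------------------------------- CV loop
@pytest.fixture(scope="module")
def summary_and_dataset(eligible_cohort):
    ds = build_scenario(eligible_cohort, 1, seed=2)
    cfg = ModelConfig(epochs=5)
    return cross_validate(ds, cfg, k=5, seed=2), ds


class TestCrossValidate:

    def test_five_folds_and_aggregation_identity(self, summary_and_dataset):
        summary, _ = summary_and_dataset
        assert len(summary.folds) == 5
        accs = [f.accuracy for f in summary.folds]
        assert summary.mean["accuracy"] == pytest.approx(np.mean(accs))
        assert summary.sd["accuracy"] == pytest.approx(np.std(accs, ddof=1))

    def test_eval_folds_cover_dataset(self, summary_and_dataset):
        summary, ds = summary_and_dataset
        assert sum(f.n_eval for f in summary.folds) == len(ds)
        assert summary.n_total == len(ds)

    def test_best_fold_has_max_accuracy(self, summary_and_dataset):
        summary, _ = summary_and_dataset
        accs = [f.accuracy for f in summary.folds]
        assert accs[summary.best_fold] == max(accs)

    def test_both_significance_tests_reported(self, summary_and_dataset):
        summary, _ = summary_and_dataset
        assert np.isfinite(summary.chi2_statistic)
        assert 0 <= summary.chi2_p <= 1
        assert 0 <= summary.proportion_p <= 1
        assert 0 <= summary.fold_t_p <= 1

    def test_determinism(self, eligible_cohort):
        ds = build_scenario(eligible_cohort, 1, seed=2)
        cfg = ModelConfig(epochs=2)
        s1 = cross_validate(ds, cfg, k=5, seed=7)
        s2 = cross_validate(ds, cfg, k=5, seed=7)
        assert s1.to_dict() == s2.to_dict()

    def test_report_files_written(self, summary_and_dataset, tmp_path):
        summary, _ = summary_and_dataset
        summary.write(tmp_path, prefix="s1")
        assert (tmp_path / "s1_folds.csv").exists()
        assert (tmp_path / "s1_summary.yaml").exists()
        assert (tmp_path / "s1_best_confusion_normalized.csv").exists()
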