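"""Stratified cross-validation, the metric suite and significance tests.

Metrics follow the two-class conventions used throughout the analysis:
accuracy, macro F1, macro sensitivity (unweighted mean per-class recall),
macro one-vs-rest AUC (equal to the ordinary rank-sum AUC for two classes,
ties credited 1/2), and a rows-are-truth confusion matrix. Significance is
assessed with a Pearson chi-squared test of independence on the best fold's
confusion matrix (no continuity correction), a one-sample proportion z-test
of pooled accuracy against the 50% chance baseline, and a one-sample t-test
of the per-fold accuracies against 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .cohort import ScenarioDataset
from .model import ModelConfig, predict, train_fold


class UndefinedTestError(ValueError):
    """The requested statistic is undefined for the given inputs."""


@dataclass(frozen=True)
class FoldMetrics:
    accuracy: float
    f1_macro: float
    sensitivity_macro: float
    auc_macro: float
    confusion: tuple[tuple[int, int], tuple[int, int]]
    n_eval: int

    def confusion_array(self) -> np.ndarray:
        return np.asarray(self.confusion, dtype=int)

    def normalized_confusion(self) -> np.ndarray:
        """Row-normalized confusion: each true class sums to 1."""
        c = self.confusion_array().astype(float)
        return c / c.sum(axis=1, keepdims=True)


METRIC_NAMES = ("accuracy", "f1_macro", "sensitivity_macro", "auc_macro")


@dataclass
class CVSummary:
    folds: list[FoldMetrics]
    mean: dict[str, float]
    sd: dict[str, float]
    best_fold: int
    chi2_statistic: float
    chi2_p: float
    proportion_z: float
    proportion_p: float
    fold_t_statistic: float
    fold_t_p: float
    pooled_accuracy: float
    n_total: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["folds"] = [asdict(f) for f in self.folds]
        return d

    def fold_table(self) -> pd.DataFrame:
        rows = [{m: getattr(f, m) for m in METRIC_NAMES} for f in self.folds]
        return pd.DataFrame(rows, index=[f"fold{i}" for i in range(len(self.folds))])

    def write(self, out_dir: str | Path, prefix: str = "cv") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.fold_table().to_csv(out_dir / f"{prefix}_folds.csv")
        summary = {k: v for k, v in self.to_dict().items() if k != "folds"}
        (out_dir / f"{prefix}_summary.yaml").write_text(
            yaml.safe_dump(summary, sort_keys=False)
        )
        norm = self.folds[self.best_fold].normalized_confusion()
        pd.DataFrame(
            norm,
            index=["true_0", "true_1"],
            columns=["pred_0", "pred_1"],
        ).to_csv(out_dir / f"{prefix}_best_confusion_normalized.csv")


def stratified_kfold(
    dataset: ScenarioDataset | np.ndarray, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint stratified (train, eval) index splits.

    The evaluation folds partition all indices and per-class counts across
    folds differ by at most one. Deterministic given ``seed``.
    """
    y = dataset.labels if isinstance(dataset, ScenarioDataset) else np.asarray(dataset)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratified {k}-fold requires >= {k} members per class, got {counts.tolist()}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, test) for train, test in splitter.split(np.zeros(len(y)), y)]


def compute_metrics(
    true_labels: Sequence[int], predicted_labels: Sequence[int], scores: Sequence[float]
) -> FoldMetrics:
    """Full metric set for one evaluation split; scores are class-1 probabilities."""
    y = np.asarray(true_labels, int)
    yhat = np.asarray(predicted_labels, int)
    s = np.asarray(scores, float)
    if not (len(y) == len(yhat) == len(s)):
        raise ValueError("true labels, predictions and scores must have equal length")
    if np.unique(y).size < 2:
        raise UndefinedTestError("AUC is undefined with a single true class")
    confusion = confusion_matrix(y, yhat, labels=[0, 1])
    return FoldMetrics(
        accuracy=float(accuracy_score(y, yhat)),
        f1_macro=float(f1_score(y, yhat, average="macro", zero_division=0)),
        sensitivity_macro=float(recall_score(y, yhat, average="macro")),
        auc_macro=float(roc_auc_score(y, s)),
        confusion=tuple(tuple(int(v) for v in row) for row in confusion),
        n_eval=len(y),
    )


def metrics_from_recalls(
    recall_class0: float, recall_class1: float, n_class0: int, n_class1: int
) -> FoldMetrics:
    """Reconstruct fold metrics from published per-class recall rates.

    Builds the integer confusion matrix implied by the two recalls and the
    class sizes and scores it with :func:`compute_metrics`; the ranking
    scores are placed so that the AUC is consistent with the hard labels
    (ties broken as in the confusion matrix). Used to check printed
    confusion-matrix rates against printed macro sensitivities.
    """
    c00 = int(round(recall_class0 * n_class0))
    c11 = int(round(recall_class1 * n_class1))
    y = np.concatenate([np.zeros(n_class0, int), np.ones(n_class1, int)])
    yhat = np.concatenate([
        np.zeros(c00, int), np.ones(n_class0 - c00, int),
        np.zeros(n_class1 - c11, int), np.ones(c11, int),
    ])
    return compute_metrics(y, yhat, yhat.astype(float))


def chi_squared_confusion(confusion) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a 2x2 confusion table."""
    table = np.asarray(confusion, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("confusion must be a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise UndefinedTestError("chi-squared undefined with a zero marginal total")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def proportion_z_test(
    accuracy: float, n: int, p0: float = 0.5
) -> tuple[float, float]:
    """One-sample proportion z-test of an accuracy against a chance baseline.

    z = (accuracy - p0) / sqrt(p0 (1 - p0) / n), with a two-sided normal p.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    z = (accuracy - p0) / np.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def cross_validate(
    dataset: ScenarioDataset, model_config: ModelConfig, k: int = 5, seed: int = 0
) -> CVSummary:
    """Train and evaluate one model per stratified fold; aggregate mean +/- SD.

    Per-fold training seeds are derived deterministically from ``seed``. The
    proportion z-test is applied to the pooled out-of-fold predictions
    (n = dataset size); the chi-squared test to the best fold's confusion
    matrix (best = highest fold accuracy, first on ties); a one-sample
    t-test compares the k fold accuracies to the 0.5 baseline.
    """
    splits = stratified_kfold(dataset, k=k, seed=seed)
    fold_seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)
    arrays = dataset.to_arrays()

    folds: list[FoldMetrics] = []
    pooled_correct = 0
    for (train_idx, eval_idx), fold_seed in zip(splits, fold_seeds):
        cfg = ModelConfig.from_dict({**model_config.to_dict(), "seed": int(fold_seed)})
        train_arrays = {key: v[train_idx] for key, v in arrays.items()}
        eval_arrays = {key: v[eval_idx] for key, v in arrays.items()}
        model = train_fold(train_arrays, cfg)
        yhat, scores = predict(model, eval_arrays)
        fm = compute_metrics(eval_arrays["y"], yhat, scores)
        folds.append(fm)
        pooled_correct += int(round(fm.accuracy * fm.n_eval))

    accs = np.array([f.accuracy for f in folds])
    mean = {m: float(np.mean([getattr(f, m) for f in folds])) for m in METRIC_NAMES}
    sd = {m: float(np.std([getattr(f, m) for f in folds], ddof=1)) for m in METRIC_NAMES}
    best = int(np.argmax(accs))
    chi2_stat, chi2_p = chi_squared_confusion(folds[best].confusion_array())
    n_total = int(sum(f.n_eval for f in folds))
    pooled_acc = pooled_correct / n_total
    z, zp = proportion_z_test(pooled_acc, n_total)
    t_res = stats.ttest_1samp(accs, 0.5)
    return CVSummary(
        folds=folds,
        mean=mean,
        sd=sd,
        best_fold=best,
        chi2_statistic=chi2_stat,
        chi2_p=chi2_p,
        proportion_z=z,
        proportion_p=zp,
        fold_t_statistic=float(t_res.statistic),
        fold_t_p=float(t_res.pvalue),
        pooled_accuracy=float(pooled_acc),
        n_total=n_total,
    )
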