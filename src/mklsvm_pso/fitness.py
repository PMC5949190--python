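"""Cross-validated fitness and recognition metrics.

The swarm (and the grid baseline) score a hyperparameter point
``(C, g, m, d)`` by k-fold cross-validated recognition accuracy on the
training table, in percent:

    ACC = 100 * (TP + TN) / (TP + TN + FP + FN)
    SEN = 100 * TP / (TP + FN)

with +1 (nodule) as the positive class.  Folds are stratified so the
80-vs-190 style class imbalance is preserved in every fold, features are
z-scored with training-fold statistics only, and the fold-wise confusion
counts are pooled before taking the ratio — so the fitness is a rational
number such as 160/170 = 94.1176%, matching the printed precision this
kind of protocol reports.  Given the same data, hyperparameters, fold
count and seed the fitness is byte-identical across calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureDataset
from .kernels import KernelParams, gram_matrix
from .svm import ConvergenceError, SVMModel, predict, train_svm

__all__ = [
    "ConfusionCounts",
    "HyperParams",
    "UndefinedMetricError",
    "confusion_counts",
    "acc",
    "sen",
    "stratified_folds",
    "cv_fitness",
    "zscore_fit",
    "zscore_apply",
    "train_and_evaluate",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (distinct from a legitimate zero)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class HyperParams:
    """A candidate solution: regularization C plus mixed-kernel parameters."""

    C: float
    kernel_params: KernelParams

    def __post_init__(self):
        if not self.C > 0:
            raise ValueError(f"C must be > 0, got {self.C}")


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Binary confusion counts with +1 = positive (nodule)."""
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    pos = y_true == 1
    pred_pos = y_pred == 1
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def acc(c: ConfusionCounts) -> float:
    """Recognition accuracy, percent."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined on zero samples")
    return 100.0 * (c.tp + c.tn) / c.total


def sen(c: ConfusionCounts) -> float:
    """Sensitivity TP/(TP+FN), percent; undefined without positives."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined without positive samples")
    return 100.0 * c.tp / (c.tp + c.fn)


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Each class is shuffled with its own slice of the seeded stream and
    dealt round-robin; a running offset keeps overall fold sizes within
    one of each other as well as per class.
    """
    y = np.asarray(y).astype(int).ravel()
    if k < 2:
        raise ValueError(f"fold count must be >= 2, got {k}")
    folds = np.empty(y.shape[0], dtype=int)
    rng = np.random.default_rng(seed)
    offset = 0
    for label in (1, -1):
        idx = np.flatnonzero(y == label)
        if idx.size < k:
            raise ValueError(
                f"class {label:+d} has {idx.size} samples, fewer than k={k} folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = (offset + np.arange(idx.size)) % k
        offset += idx.size
    return folds


def zscore_fit(X) -> tuple[np.ndarray, np.ndarray]:
    """Column means and stds for standardization; constant columns get sd 1."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def zscore_apply(X, mu, sd) -> np.ndarray:
    return (np.asarray(X, dtype=float) - mu) / sd


def cv_fitness(data: FeatureDataset, hp: HyperParams, k: int, seed: int) -> float:
    """k-fold cross-validated ACC (percent) of the mixed-kernel SVM at ``hp``.

    Confusion counts are pooled across the k out-of-fold predictions and a
    single accuracy is taken at the end.  Z-scoring uses training-fold
    statistics only.  Deterministic in (data, hp, k, seed).
    """
    folds = stratified_folds(data.y, k, seed)
    total = ConfusionCounts(0, 0, 0, 0)
    for f in range(k):
        va = folds == f
        tr = ~va
        mu, sd = zscore_fit(data.X[tr])
        Ztr = zscore_apply(data.X[tr], mu, sd)
        Zva = zscore_apply(data.X[va], mu, sd)
        p = hp.kernel_params
        K_tr = gram_matrix(Ztr, Ztr, p)
        K_va = gram_matrix(Ztr, Zva, p)
        try:
            model = train_svm(K_tr, data.y[tr], hp.C, kernel_params=p)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"solver failed in CV fold {f}: {err}", model=err.model
            ) from err
        total = total + confusion_counts(data.y[va], predict(model, K_va))
    return acc(total)


def train_and_evaluate(
    train: FeatureDataset, test: FeatureDataset, hp: HyperParams
) -> tuple[float, float, ConfusionCounts, SVMModel]:
    """Fit on the full training table and score the held-out test table.

    Returns (ACC%, SEN%, confusion counts, fitted model).  The test table
    is standardized with the training statistics.
    """
    mu, sd = zscore_fit(train.X)
    Ztr = zscore_apply(train.X, mu, sd)
    Zte = zscore_apply(test.X, mu, sd)
    p = hp.kernel_params
    model = train_svm(gram_matrix(Ztr, Ztr, p), train.y, hp.C, kernel_params=p)
    counts = confusion_counts(test.y, predict(model, gram_matrix(Ztr, Zte, p)))
    return acc(counts), sen(counts), counts, model
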