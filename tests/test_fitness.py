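"""Confusion metrics, stratified folds and the cross-validated fitness."""

import numpy as np
import pytest

from mklsvm_pso import (
    ConfusionCounts,
    FeatureDataset,
    HyperParams,
    KernelParams,
    acc,
    confusion_counts,
    cv_fitness,
    sen,
    stratified_folds,
)
from mklsvm_pso.fitness import UndefinedMetricError, train_and_evaluate
from mklsvm_pso.synthetic import generate_gaussian_classes, generate_ring_classes


def test_confusion_counts_examples():
    c = confusion_counts([1, 1, -1, -1], [1, -1, -1, 1])
    assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)
    y = [1] * 6 + [-1] * 4
    c = confusion_counts(y, y)
    assert (c.tp, c.tn, c.fp, c.fn) == (6, 4, 0, 0)
    # flipping all predictions swaps TP<->FN and TN<->FP
    flipped = confusion_counts(y, [-v for v in y])
    assert (flipped.tp, flipped.fn) == (c.fn, c.tp)
    assert (flipped.tn, flipped.fp) == (c.fp, c.tn)
    with pytest.raises(ValueError):
        confusion_counts([1, -1], [1])


@pytest.mark.parametrize(
    "counts, expected",
    [
        (ConfusionCounts(16, 1, 0, 0), 100 * 16 / 17),
        (ConfusionCounts(5, 0, 5, 0), 100.0),
        (ConfusionCounts(0, 3, 0, 2), 0.0),
    ],
)
def test_acc_examples(counts, expected):
    assert acc(counts) == pytest.approx(expected)


@pytest.mark.parametrize(
    "counts, expected",
    [
        (ConfusionCounts(8, 0, 0, 1), 100 * 8 / 9),  # prints as 88.89%
        (ConfusionCounts(3, 2, 1, 0), 100.0),
        (ConfusionCounts(0, 0, 1, 5), 0.0),
    ],
)
def test_sen_examples(counts, expected):
    assert sen(counts) == pytest.approx(expected)


def test_undefined_metrics_raise():
    with pytest.raises(UndefinedMetricError):
        acc(ConfusionCounts(0, 0, 0, 0))
    with pytest.raises(UndefinedMetricError):
        sen(ConfusionCounts(0, 3, 2, 0))


def test_acc_invariant_to_relabeling_sen_not():
    y_true = np.array([1, 1, 1, -1, -1])
    y_pred = np.array([1, -1, 1, -1, 1])
    c = confusion_counts(y_true, y_pred)
    c_swapped = confusion_counts(-y_true, -y_pred)
    assert acc(c) == pytest.approx(acc(c_swapped))
    assert sen(c) != pytest.approx(sen(c_swapped))


def test_stratified_folds_balanced_small():
    y = np.array([1] * 5 + [-1] * 5)
    folds = stratified_folds(y, k=5, seed=0)
    for f in range(5):
        sel = folds == f
        assert sel.sum() == 2
        assert np.sum(y[sel] == 1) == 1


def test_stratified_folds_protocol_sizes():
    # 170 training samples in 5 folds -> five folds of 34
    y = np.array([1] * 50 + [-1] * 120)
    folds = stratified_folds(y, k=5, seed=3)
    sizes = sorted(np.sum(folds == f) for f in range(5))
    assert sizes == [34] * 5
    # per-class sizes within 1
    pos_sizes = [int(np.sum((folds == f) & (y == 1))) for f in range(5)]
    assert max(pos_sizes) - min(pos_sizes) <= 1


def test_stratified_folds_deterministic_and_errors():
    y = np.array([1] * 10 + [-1] * 13)
    f1 = stratified_folds(y, 4, seed=9)
    f2 = stratified_folds(y, 4, seed=9)
    assert np.array_equal(f1, f2)
    assert not np.array_equal(f1, stratified_folds(y, 4, seed=10))
    with pytest.raises(ValueError):
        stratified_folds(np.array([1, 1, 1, -1, -1]), k=3, seed=0)


def _default_hp(C=1.0, m=0.5, g=1.0, d=2):
    return HyperParams(C=C, kernel_params=KernelParams(m=m, d=d, g=g))


def test_cv_fitness_separated_fixture_is_100():
    data = generate_gaussian_classes(n_pos=30, n_neg=40, dims=4, separation=10.0, seed=0)
    assert cv_fitness(data, _default_hp(g=3.0), k=5, seed=0) == pytest.approx(100.0)


def test_cv_fitness_deterministic():
    data = generate_ring_classes(n_pos=25, n_neg=40, seed=4)
    hp = _default_hp()
    assert cv_fitness(data, hp, 5, seed=11) == cv_fitness(data, hp, 5, seed=11)


def test_cv_fitness_permuted_labels_near_majority_rate():
    """Destroying the feature-label link drops fitness to about the
    majority-class rate (the classifier can do no better than chance)."""
    data = generate_ring_classes(seed=7)
    rng = np.random.default_rng(7)
    permuted = FeatureDataset(data.X, rng.permutation(data.y))
    fit = cv_fitness(permuted, _default_hp(), 5, seed=0)
    majority = 100 * 190 / 270
    assert abs(fit - majority) <= 12.0


def test_cv_fitness_no_structure_cannot_beat_majority():
    """With zero class separation the out-of-fold accuracy cannot
    systematically exceed the majority rate (binomial-noise margin)."""
    majority = 100 * 190 / 270
    sd = 100 * np.sqrt(0.7 * 0.3 / 270)
    for seed in range(3):
        data = generate_gaussian_classes(separation=0.0, seed=seed)
        fit = cv_fitness(data, _default_hp(C=0.1, g=3.0), 5, seed=seed)
        assert fit <= majority + 3 * sd
        assert fit >= 40.0


def test_pooled_acc_equals_weighted_fold_mean():
    """Pooled-count ACC is the sample-weighted mean of per-fold ACCs."""
    data = generate_ring_classes(n_pos=25, n_neg=40, seed=1)
    hp = _default_hp()
    k, seed = 5, 2
    pooled = cv_fitness(data, hp, k, seed)
    # recompute fold-by-fold with the same deterministic machinery
    from mklsvm_pso.fitness import zscore_apply, zscore_fit
    from mklsvm_pso import gram_matrix, predict, train_svm, confusion_counts as cc

    folds = stratified_folds(data.y, k, seed)
    weighted = 0.0
    for f in range(k):
        va, tr = folds == f, folds != f
        mu, sd = zscore_fit(data.X[tr])
        Ztr, Zva = zscore_apply(data.X[tr], mu, sd), zscore_apply(data.X[va], mu, sd)
        model = train_svm(gram_matrix(Ztr, Ztr, hp.kernel_params), data.y[tr], hp.C)
        c = cc(data.y[va], predict(model, gram_matrix(Ztr, Zva, hp.kernel_params)))
        weighted += acc(c) * c.total
    assert pooled == pytest.approx(weighted / len(data), rel=1e-12)


def test_rbf_dominant_mix_beats_poly_dominant_on_rings():
    """On the radially separated fixture the RBF-heavy mix (m=0.2) does at
    least as well on average as the polynomial-heavy mix (m=0.99)."""
    poly_fits, rbf_fits = [], []
    for seed in range(10):
        data = generate_ring_classes(seed=seed)
        poly_fits.append(cv_fitness(data, _default_hp(m=0.99), 5, seed))
        rbf_fits.append(cv_fitness(data, _default_hp(m=0.2), 5, seed))
    assert np.mean(rbf_fits) >= np.mean(poly_fits)


def test_train_and_evaluate_returns_consistent_counts():
    data = generate_gaussian_classes(n_pos=30, n_neg=40, dims=4, separation=8.0, seed=5)
    from mklsvm_pso import split_train_test

    train, test = split_train_test(data, n_train=50, seed=0)
    a, s, counts, model = train_and_evaluate(train, test, _default_hp(g=3.0))
    assert counts.total == len(test)
    assert a == pytest.approx(acc(counts))
    assert s == pytest.approx(sen(counts))
    assert model.support_indices.size > 0
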