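"""Metric oracles: confusion arithmetic, AUC concordance, ECE, paired tests."""

import numpy as np
import pytest
from scipy import stats

from neutrokd.evaluation import (
    CvSummary,
    FoldReport,
    classification_metrics,
    compare_folds,
    expected_calibration_error,
    roc_curves,
    run_cross_validation,
)
from neutrokd.synthetic import LabeledImageSet


def brute_force_auc(y, scores):
    """Pairwise concordance count over all positive-negative pairs."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _prob_from_scores(scores):
    return np.column_stack([1 - scores, scores])


def test_perfect_predictions():
    y = np.array([0, 1, 2, 0, 1, 2])
    probs = np.eye(3)[y] * (1 - 1e-9) + 1e-9 / 3
    r = classification_metrics(y, probs)
    for m in ("accuracy", "sensitivity", "specificity", "precision", "recall", "f1", "auc_macro"):
        assert r.metric(m) == pytest.approx(1.0, abs=1e-6)
    assert r.log_loss < 1e-6
    assert r.ece < 1e-6


def test_macro_specificity_from_binary_confusion():
    # confusion [[8,2],[3,7]]: class-0 specificity 7/10, class-1 specificity 8/10
    y = np.array([0] * 10 + [1] * 10)
    pred = np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7)
    probs = np.where(pred[:, None] == np.arange(2), 0.9, 0.1)
    r = classification_metrics(y, probs)
    assert r.specificity == pytest.approx(0.75, abs=1e-9)
    np.testing.assert_array_equal(r.confusion, [[8, 2], [3, 7]])


def test_balanced_macro_recall_equals_accuracy(rng):
    y = np.repeat(np.arange(4), 25)
    probs = rng.exponential(1, (100, 4))
    probs /= probs.sum(1, keepdims=True)
    r = classification_metrics(y, probs)
    assert r.recall == pytest.approx(r.accuracy, abs=1e-9)
    assert r.sensitivity == r.recall


def test_confusion_sums_to_test_size(rng):
    y = rng.integers(0, 3, 50)
    probs = rng.exponential(1, (50, 3))
    probs /= probs.sum(1, keepdims=True)
    r = classification_metrics(y, probs)
    assert r.confusion.sum() == 50


def test_absent_class_excluded_with_warning(caplog):
    y = np.array([0, 0, 1, 1])  # class 2 absent
    probs = np.full((4, 3), 1 / 3)
    with caplog.at_level("WARNING"):
        r = classification_metrics(y, probs)
    assert "absent" in caplog.text
    assert np.isfinite(r.recall)


def test_ece_zero_for_calibrated_predictor():
    # per-bin confidence equals per-bin accuracy by construction
    n = 1000
    conf = 0.7
    y = np.array([0] * int(n * conf) + [1] * (n - int(n * conf)))
    probs = np.column_stack([np.full(n, conf), np.full(n, 1 - conf)])
    assert expected_calibration_error(y, probs) == pytest.approx(0.0, abs=1e-9)


def test_auc_worked_example():
    y = np.array([1, 1, 0, 0])
    scores = np.array([0.9, 0.4, 0.6, 0.2])
    curves, macro = roc_curves(y, _prob_from_scores(scores))
    assert curves[1][2] == pytest.approx(0.75, abs=1e-9)
    assert brute_force_auc(y, scores) == pytest.approx(0.75)


def test_auc_matches_brute_force_on_random_toys(rng):
    for _ in range(100):
        n = int(rng.integers(4, 21))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        scores = rng.uniform(0, 1, n)
        _, macro = roc_curves(y, _prob_from_scores(scores))
        # macro = mean of class-0 AUC (on 1-scores) and class-1 AUC (equal)
        assert macro == pytest.approx(brute_force_auc(y, scores), abs=1e-9)


def test_roc_chance_and_errors(rng):
    y = np.array([0, 1] * 10)
    const = _prob_from_scores(np.full(20, 0.5))
    _, macro = roc_curves(y, const)
    assert macro == pytest.approx(0.5)
    with pytest.raises(ValueError):
        roc_curves(np.zeros(5, int), const[:5])


def _summary_from_values(vals):
    reports = [
        FoldReport(i, v, v, v, v, v, v, v, 0.1, 0.01, np.zeros((2, 2), int))
        for i, v in enumerate(vals)
    ]
    return CvSummary(per_fold=reports, cumulative_confusion=np.zeros((2, 2), int))


def test_wilcoxon_constant_shift_exact():
    a = _summary_from_values([0.80, 0.82, 0.85, 0.79, 0.81])
    b = _summary_from_values([0.70, 0.72, 0.75, 0.69, 0.71])
    t_p, w_p = compare_folds(a, b, "accuracy")
    assert w_p == pytest.approx(0.0625, abs=1e-12)  # 2/2^5, exact enumeration
    assert 0 < t_p < 1


def test_compare_identical_folds_and_symmetry():
    a = _summary_from_values([0.8, 0.81, 0.79, 0.8, 0.82])
    assert compare_folds(a, a, "accuracy") == (1.0, 1.0)
    b = _summary_from_values([0.7, 0.84, 0.74, 0.83, 0.78])
    ab = compare_folds(a, b, "accuracy")
    ba = compare_folds(b, a, "accuracy")
    assert ab == pytest.approx(ba)


def test_ci95_formula():
    vals = [0.8286, 0.8857, 0.8000, 0.8143, 0.8714]
    s = _summary_from_values(vals)
    mean = np.mean(vals)
    half = stats.t.ppf(0.975, 4) * np.std(vals, ddof=1) / np.sqrt(5)
    assert s.summary.loc["accuracy", "ci95_low"] == pytest.approx(mean - half, abs=1e-9)
    assert s.summary.loc["accuracy", "ci95_high"] == pytest.approx(mean + half, abs=1e-9)


def _toy_image_set(n_per_class=6, n_classes=3):
    rng = np.random.default_rng(0)
    images, labels = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            img = np.full((32, 32, 3), 40 * (c + 1), np.uint8)
            img += rng.integers(0, 10, img.shape).astype(np.uint8)
            images.append(img)
            labels.append(c)
    return LabeledImageSet(images, np.array(labels), [f"c{i}" for i in range(n_classes)])


def test_cross_validation_folds_partition_and_determinism():
    ds = _toy_image_set(n_per_class=10)
    seen = []

    def fit_predict(train, test, fold):
        seen.append((len(train), len(test), tuple(test.labels)))
        # predict by mean intensity band: a deterministic stand-in classifier
        probs = np.zeros((len(test), ds.n_classes))
        for i, img in enumerate(test.images):
            probs[i, min(int(img.mean() // 40) - 1, 2)] = 1.0
        probs += 1e-9
        return probs / probs.sum(1, keepdims=True)

    s1 = run_cross_validation(ds, fit_predict, n_splits=5, seed=42)
    assert len(s1.per_fold) == 5
    assert all(np.bincount(np.array(t[2])).tolist() == [2, 2, 2] for t in seen)
    assert s1.cumulative_confusion.sum() == len(ds)
    seen2 = []

    def fp2(train, test, fold):
        seen2.append(tuple(test.labels))
        return fit_predict(train, test, fold)

    run_cross_validation(ds, fp2, n_splits=5, seed=42)
    assert [t[2] for t in seen[:5]] == seen2  # identical fold assignment on rerun


def test_cross_validation_rejects_tiny_classes():
    ds = _toy_image_set(n_per_class=3)
    with pytest.raises(ValueError):
        run_cross_validation(ds, lambda a, b, c: None, n_splits=5)


def test_row_normalized_cumulative_confusion():
    conf = np.array([[8, 2], [1, 9]], dtype=float)
    norm = conf / conf.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(norm.sum(axis=1), 1.0)
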