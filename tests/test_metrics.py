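import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from actidep.metrics import (
    ConfusionMatrix,
    FoldResults,
    accuracy,
    classification_report,
    confusion,
    f1,
    kfold_cv,
    kfold_indices,
    parse_report,
    precision,
    recall,
    report_from_confusion,
    roc_auc,
    sensitivity,
    specificity,
)

# Held-out confusion matrix reconstructed from the published per-class
# recalls and supports: 33/44 = 0.75 depressed, 57/72 = 0.79 not depressed.
HELD_OUT_CM = ConfusionMatrix(tp=33, tn=57, fp=15, fn=11)


def mann_whitney_auc(scores, y):
    """Brute-force rank statistic P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_enumerated_four_pairs(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)
        assert cm.cp == 2 and cm.cn == 2 and cm.n == 4

    def test_perfect_prediction(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert cm.fp == 0 and cm.fn == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, 30)
        y_pred = rng.integers(0, 2, 30)
        cm = confusion(y_true, y_pred)
        np.testing.assert_array_equal(
            cm.as_array(), sk_confusion(y_true, y_pred, labels=[0, 1])
        )


class TestRatioMetrics:
    def test_held_out_matrix_metrics(self):
        cm = HELD_OUT_CM
        assert accuracy(cm) == pytest.approx(90 / 116)
        assert round(accuracy(cm), 2) == 0.78
        assert precision(cm) == pytest.approx(33 / 48)
        assert round(precision(cm), 2) == 0.69
        assert recall(cm) == pytest.approx(0.75)
        assert specificity(cm) == pytest.approx(57 / 72)

    def test_recall_is_sensitivity(self):
        for cm in (HELD_OUT_CM, ConfusionMatrix(3, 4, 2, 1)):
            assert recall(cm) == sensitivity(cm)

    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=5, tn=5, fp=0, fn=0)
        assert accuracy(cm) == sensitivity(cm) == specificity(cm) == 1.0

    def test_zero_denominator_warns_and_returns_zero(self):
        cm = ConfusionMatrix(tp=0, tn=4, fp=0, fn=0)
        with pytest.warns(UserWarning):
            assert precision(cm) == 0.0

    def test_zero_denominator_strict_raises(self):
        cm = ConfusionMatrix(tp=0, tn=4, fp=0, fn=0)
        with pytest.raises(ZeroDivisionError):
            precision(cm, strict=True)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=0)


class TestF1:
    def test_depressed_class_value(self):
        assert round(f1(33 / 48, 0.75), 2) == 0.72

    def test_not_depressed_class_value(self):
        assert round(f1(57 / 68, 57 / 72), 2) == 0.81

    def test_equal_precision_recall_is_identity(self):
        for x in (0.2, 0.5, 0.9):
            assert f1(x, x) == pytest.approx(x)

    def test_zero_sum_returns_zero(self):
        assert f1(0.0, 0.0) == 0.0


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_constant_scores_diagonal(self):
        roc = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.5)
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        # coarse grid of scores to force plenty of ties
        scores = rng.integers(0, 4, n) / 4.0
        roc = roc_auc(scores, y)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, y), abs=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 10)
        scores = rng.normal(size=20)
        base = roc_auc(scores, y).auc
        for transform in (lambda s: 3 * s + 1, np.tanh, lambda s: np.exp(s / 2)):
            assert roc_auc(transform(scores), y).auc == pytest.approx(base, abs=1e-12)

    def test_curve_monotone_with_proper_endpoints(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        roc = roc_auc(rng.normal(size=30), y)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestClassificationReport:
    def test_held_out_report_reproduces_published_table(self):
        report = report_from_confusion(HELD_OUT_CM)
        dep = report.per_class[1]
        ndep = report.per_class[0]
        assert (round(dep.precision, 2), round(dep.recall, 2), round(dep.f1, 2)) == (
            0.69,
            0.75,
            0.72,
        )
        assert dep.support == 44
        assert (round(ndep.precision, 2), round(ndep.recall, 2), round(ndep.f1, 2)) == (
            0.84,
            0.79,
            0.81,
        )
        assert ndep.support == 72
        assert round(report.macro.f1, 2) == 0.77
        assert round(report.macro.recall, 2) == 0.77
        assert round(report.macro.precision, 2) == 0.76
        assert round(report.weighted.precision, 2) == 0.78
        assert round(report.weighted.recall, 2) == 0.78
        assert round(report.weighted.f1, 2) == 0.78
        assert round(report.accuracy, 2) == 0.78
        assert report.weighted.support == 116

    def test_perfect_predictions(self):
        report = classification_report([0] * 5 + [1] * 5, [0] * 5 + [1] * 5)
        for m in report.per_class.values():
            assert m.precision == m.recall == m.f1 == 1.0
            assert m.support == 5
        assert report.accuracy == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn_report(self, seed):
        rng = np.random.default_rng(seed + 50)
        y_true = rng.integers(0, 2, 40)
        y_pred = rng.integers(0, 2, 40)
        y_true[:2] = [0, 1]
        y_pred[:2] = [1, 0]
        report = classification_report(y_true, y_pred)
        for avg, mine in (("macro", report.macro), ("weighted", report.weighted)):
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average=avg, zero_division=0
            )
            assert mine.precision == pytest.approx(p)
            assert mine.recall == pytest.approx(r)
            assert mine.f1 == pytest.approx(f)

    @pytest.mark.parametrize("seed", range(3))
    def test_accuracy_equals_weighted_recall(self, seed):
        rng = np.random.default_rng(seed + 90)
        y_true = rng.integers(0, 2, 25)
        y_pred = rng.integers(0, 2, 25)
        y_true[:2] = [0, 1]
        report = classification_report(y_true, y_pred)
        assert report.accuracy == pytest.approx(report.weighted.recall)

    def test_render_parse_round_trip(self):
        report = report_from_confusion(HELD_OUT_CM)
        parsed = parse_report(report.render())
        raw = report.to_dict()
        for name, key in (("Not Depressed", "0"), ("Depressed", "1")):
            for metric in ("precision", "recall", "f1"):
                assert parsed[name][metric] == round(raw["classes"][key][metric], 2)
            assert parsed[name]["support"] == raw["classes"][key]["support"]
        assert parsed["Macro avg"]["f1"] == round(raw["macro_avg"]["f1"], 2)
        assert parsed["Weighted avg"]["precision"] == round(
            raw["weighted_avg"]["precision"], 2
        )
        assert parsed["Accuracy"]["f1"] == round(raw["accuracy"], 2)


class TestKfold:
    def test_published_fold_values_aggregate(self):
        folds = FoldResults(accuracies=(0.70, 0.83, 0.90), losses=(0.48, 0.34, 0.27))
        assert folds.mean_accuracy == pytest.approx(0.81)
        assert round(folds.mean_accuracy, 2) == 0.81
        assert folds.mean_loss == pytest.approx(0.363333, abs=1e-6)
        assert round(folds.mean_loss, 2) == 0.36

    def test_folds_partition_the_data(self):
        folds = kfold_indices(20, 3, seed=1)
        flat = np.concatenate(folds)
        assert len(flat) == 20
        assert sorted(flat.tolist()) == list(range(20))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(2, 3, seed=0)

    def test_kfold_cv_trains_on_complement(self):
        X = np.arange(12).reshape(12, 1).astype(float)
        y = np.array([0, 1] * 6)
        seen = []

        def fit_eval(Xtr, ytr, Xval, yval, fold):
            seen.append((set(Xtr[:, 0]), set(Xval[:, 0])))
            return 1.0, 0.0

        results = kfold_cv(X, y, fit_eval, k=3, seed=2)
        assert results.accuracies == (1.0, 1.0, 1.0)
        for train_ids, val_ids in seen:
            assert train_ids.isdisjoint(val_ids)
            assert train_ids | val_ids == set(range(12))
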