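"""Splitting, MSVM training, metric formulas, AUC, aggregation."""

import math

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from mammotv import (
    ConfusionMatrix,
    SplitSpec,
    SvmConfig,
    aggregate,
    confusion,
    evaluate_split,
    per_class_metrics,
    roc_auc,
    split_dataset,
    train_msvm,
)
from mammotv.errors import StratificationError, ValidationError


class _Labeled:
    """Minimal label carrier accepted by split_dataset."""

    def __init__(self, label):
        self.label = label


def _labelled(counts):
    out = []
    for label, n in counts.items():
        out.extend(_Labeled(label) for _ in range(n))
    return out


class TestSplitDataset:
    def test_canonical_416_split_at_70_percent(self):
        # floor per class: 210 + 46 + 35 = 291 train, remainder 125 test
        patches = _labelled({"normal": 300, "benign": 66, "malignant": 50})
        train, test = split_dataset(patches, SplitSpec(0.7, seed=0))
        assert (len(train), len(test)) == (291, 125)
        assert sorted(train + test) == list(range(416))
        assert not set(train) & set(test)

    def test_small_class_at_90_percent(self):
        patches = _labelled({"normal": 10, "benign": 10})
        train, test = split_dataset(patches, SplitSpec(0.9, seed=1))
        train_normals = sum(1 for i in train if patches[i].label == "normal")
        assert train_normals == 9
        assert len(train) == 18 and len(test) == 2

    def test_per_class_proportions_preserved(self):
        patches = _labelled({"normal": 100, "benign": 40, "malignant": 20})
        train, _ = split_dataset(patches, SplitSpec(0.8, seed=3))
        for label, n in (("normal", 100), ("benign", 40), ("malignant", 20)):
            got = sum(1 for i in train if patches[i].label == label)
            assert got == int(0.8 * n)

    def test_same_seed_identical_partitions(self):
        patches = _labelled({"normal": 20, "benign": 10, "malignant": 8})
        assert split_dataset(patches, SplitSpec(0.7, seed=9)) == split_dataset(
            patches, SplitSpec(0.7, seed=9)
        )

    def test_class_below_two_members_rejected(self):
        patches = _labelled({"normal": 5, "malignant": 1})
        with pytest.raises(StratificationError):
            split_dataset(patches, SplitSpec(0.7, seed=0))


class TestTrainMsvm:
    def test_separable_clouds_train_to_perfection(self):
        rng = np.random.default_rng(0)
        a = rng.normal(loc=0.0, size=(30, 4))
        b = rng.normal(loc=10.0, size=(30, 4))
        values = np.vstack([a, b])
        labels = ["normal"] * 30 + ["benign"] * 30
        model = train_msvm(values, labels, SvmConfig())
        assert model.predict(values) == labels

    def test_three_class_decision_scores_shape(self):
        rng = np.random.default_rng(1)
        values = np.vstack(
            [rng.normal(loc=c * 8.0, size=(15, 3)) for c in range(3)]
        )
        labels = ["normal"] * 15 + ["benign"] * 15 + ["malignant"] * 15
        model = train_msvm(values, labels)
        scores = model.decision_scores(values)
        assert scores.shape == (45, 3)
        assert np.isfinite(scores).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train_msvm(np.ones((5, 2)), ["normal"] * 5)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            train_msvm(np.empty((0, 4)), [])


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = ["normal", "benign", "malignant", "normal"]
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_single_predicted_class_fills_one_column(self):
        y_true = ["normal", "benign", "malignant"]
        cm = confusion(y_true, ["benign"] * 3)
        assert cm.counts[:, 1].tolist() == [1, 1, 1]
        assert cm.counts.sum() == 3

    def test_total_conserved_on_random_labels(self):
        rng = np.random.default_rng(5)
        classes = np.array(["normal", "benign", "malignant"])
        y_true = classes[rng.integers(0, 3, 200)].tolist()
        y_pred = classes[rng.integers(0, 3, 200)].tolist()
        cm = confusion(y_true, y_pred)
        assert cm.total == 200
        # brute-force pairwise count
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                want = sum(1 for t, p in zip(y_true, y_pred) if t == ci and p == cj)
                assert cm.counts[i, j] == want

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion(["normal"], ["weird"])


class TestPerClassMetrics:
    def test_binary_hand_computed_cells(self):
        # TP=4, FN=2, FP=1, TN=5 for the first class
        cm = ConfusionMatrix(np.array([[4, 2], [1, 5]]), class_order=("pos", "neg"))
        per_class, accuracy, undefined = per_class_metrics(cm)
        m = per_class["pos"]
        assert m["recall"] == pytest.approx(0.6667, abs=1e-4)
        assert m["precision"] == pytest.approx(0.8000, abs=1e-4)
        assert m["specificity"] == pytest.approx(0.8333, abs=1e-4)
        assert m["accuracy"] == pytest.approx(0.7500, abs=1e-4)
        assert m["f1"] == pytest.approx(0.7273, abs=1e-4)
        assert accuracy == pytest.approx(0.75)
        assert undefined == []

    def test_perfect_matrix_all_ones(self):
        cm = ConfusionMatrix(np.diag([5, 3, 2]))
        per_class, accuracy, undefined = per_class_metrics(cm)
        assert accuracy == 1.0
        for metrics in per_class.values():
            for v in metrics.values():
                assert v == 1.0

    def test_absent_class_yields_undefined_markers_not_zeros(self):
        # malignant never true and never predicted
        counts = np.array([[10, 2, 0], [1, 7, 0], [0, 0, 0]])
        per_class, _, undefined = per_class_metrics(ConfusionMatrix(counts))
        assert math.isnan(per_class["malignant"]["recall"])
        assert math.isnan(per_class["malignant"]["precision"])
        assert "recall:malignant" in undefined
        assert "precision:malignant" in undefined

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            counts = rng.integers(0, 30, size=(3, 3))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = ConfusionMatrix(counts)
            per_class, accuracy, _ = per_class_metrics(cm)
            total = counts.sum()
            assert accuracy == pytest.approx(np.trace(counts) / total)
            for k, cls in enumerate(cm.class_order):
                tp = counts[k, k]
                fn = counts[k].sum() - tp
                fp = counts[:, k].sum() - tp
                tn = total - tp - fn - fp
                m = per_class[cls]
                if tp + fn:
                    assert m["recall"] == pytest.approx(tp / (tp + fn))
                if tp + fp:
                    assert m["precision"] == pytest.approx(tp / (tp + fp))
                if tn + fp:
                    assert m["specificity"] == pytest.approx(tn / (tn + fp))
                assert m["accuracy"] == pytest.approx((tp + tn) / total)

    def test_matches_sklearn_reduction(self):
        rng = np.random.default_rng(13)
        classes = np.array(["normal", "benign", "malignant"])
        y_true = classes[rng.integers(0, 3, 300)]
        y_pred = classes[rng.integers(0, 3, 300)]
        cm = confusion(y_true.tolist(), y_pred.tolist())
        per_class, _, _ = per_class_metrics(cm)
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(cm.class_order), zero_division=np.nan
        )
        for k, cls in enumerate(cm.class_order):
            assert per_class[cls]["precision"] == pytest.approx(p[k])
            assert per_class[cls]["recall"] == pytest.approx(r[k])
            assert per_class[cls]["f1"] == pytest.approx(f1[k])


class TestRocAuc:
    def test_perfect_ordering_gives_one(self):
        y = ["normal"] * 5 + ["benign"] * 5
        scores = np.zeros((10, 3))
        scores[:5, 0] = [5, 4, 3, 2, 1]
        scores[5:, 0] = [-1, -2, -3, -4, -5]
        scores[:, 1] = -scores[:, 0]
        auc = roc_auc(y, scores)
        assert auc["normal"] == 1.0
        assert auc["benign"] == 1.0

    def test_all_tied_scores_give_half(self):
        y = ["normal"] * 4 + ["benign"] * 6
        auc = roc_auc(y, np.zeros((10, 3)))
        assert auc["normal"] == 0.5
        assert auc["benign"] == 0.5

    def test_absent_class_is_undefined(self):
        y = ["normal", "normal", "benign"]
        auc = roc_auc(y, np.zeros((3, 3)))
        assert math.isnan(auc["malignant"])

    def test_matches_exhaustive_pair_comparison(self):
        rng = np.random.default_rng(17)
        classes = ("normal", "benign", "malignant")
        for _ in range(30):
            n = int(rng.integers(6, 101))
            y = [classes[i] for i in rng.integers(0, 3, n)]
            scores = np.round(rng.normal(size=(n, 3)), 1)  # rounding forces ties
            auc = roc_auc(y, scores)
            for k, cls in enumerate(classes):
                pos = [scores[i, k] for i in range(n) if y[i] == cls]
                neg = [scores[i, k] for i in range(n) if y[i] != cls]
                if not pos or not neg:
                    assert math.isnan(auc[cls])
                    continue
                wins = sum(
                    1.0 if p > q else 0.5 if p == q else 0.0
                    for p in pos for q in neg
                )
                assert auc[cls] == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_matches_sklearn_on_tie_free_scores(self):
        rng = np.random.default_rng(19)
        y = [("normal", "benign", "malignant")[i] for i in rng.integers(0, 3, 80)]
        scores = rng.normal(size=(80, 3))
        auc = roc_auc(y, scores)
        for k, cls in enumerate(("normal", "benign", "malignant")):
            want = roc_auc_score([1 if t == cls else 0 for t in y], scores[:, k])
            assert auc[cls] == pytest.approx(want, abs=1e-12)


class TestEvaluateAndAggregate:
    @staticmethod
    def _report(seed, loc=8.0):
        rng = np.random.default_rng(seed)
        values = np.vstack(
            [rng.normal(loc=c * loc, size=(20, 5)) for c in range(3)]
        )
        labels = ["normal"] * 20 + ["benign"] * 20 + ["malignant"] * 20
        train = list(range(0, 60, 2))
        test = list(range(1, 60, 2))
        return evaluate_split(values, labels, train, test, train_fraction=0.5, seed=seed)

    def test_separable_classes_score_100_percent(self):
        report = self._report(seed=0)
        assert report.accuracy == 100.0
        assert report.macro["f1"] == 100.0
        assert report.confusion.total == 30

    def test_accuracy_matches_confusion_trace(self):
        report = self._report(seed=1, loc=0.5)
        cm = report.confusion
        assert report.accuracy == pytest.approx(100.0 * np.trace(cm.counts) / cm.total)

    def test_single_report_aggregates_to_itself(self):
        report = self._report(seed=2)
        table = aggregate([report], mode="overall")
        assert table["accuracy"].iloc[0] == pytest.approx(report.accuracy)

    def test_mean_of_two_accuracies(self):
        a, b = self._report(seed=3), self._report(seed=4, loc=0.0)
        table = aggregate([a, b], mode="overall")
        assert table["accuracy"].iloc[0] == pytest.approx((a.accuracy + b.accuracy) / 2)

    def test_per_class_mode_lists_all_classes(self):
        table = aggregate([self._report(seed=5)], mode="per_class")
        assert sorted(table.index) == ["benign", "malignant", "normal"]

    def test_empty_report_list_rejected(self):
        with pytest.raises(ValidationError):
            aggregate([], mode="overall")
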