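"""Stratified splitting, multiclass SVM, and the evaluation metric suite.

The classifier is a multiclass support vector machine (MSVM) built from
binary SVMs by one-vs-one decomposition (linear kernel by default).  Its
performance is summarised per class by a one-vs-rest reduction of the K-class
confusion matrix — for class c: TP = cm[c][c], FN = rest of row c,
FP = rest of column c, TN = everything else — and the standard formulas

    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    F1          = 2 * precision * recall / (precision + recall)

plus a one-vs-rest AUC computed by the rank-sum (Mann-Whitney) formulation
with ties counted half.  Overall classification accuracy is
trace(cm) / total.  A metric with a zero denominator is reported as NaN and
flagged in the report's ``undefined`` list — never silently coerced to 0,
which would corrupt averages.  All report percentages are on the 0-100 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

from .errors import StratificationError, ValidationError
from .mias import CLASS_ORDER, Patch

__all__ = [
    "SplitSpec",
    "SvmConfig",
    "ConfusionMatrix",
    "EvalReport",
    "split_dataset",
    "train_msvm",
    "MsvmModel",
    "confusion",
    "per_class_metrics",
    "roc_auc",
    "evaluate_split",
    "aggregate",
]

TRAIN_FRACTIONS = (0.70, 0.80, 0.90)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified holdout split: per-class floor(train_fraction * n) rows go
    to train, the remainder to test; deterministic given ``seed``."""

    train_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "linear"
    c: float = 1.0
    gamma: str | float = "scale"


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValidationError(f"confusion matrix must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValidationError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    """One classifier evaluation: confusion matrix, per-class and averaged
    metrics (percent), AUC, and the split/subset description."""

    tissue: str
    train_fraction: float
    seed: int
    subset_width: int
    confusion: ConfusionMatrix
    accuracy: float  # percent
    per_class: dict[str, dict[str, float]]  # percent; NaN when undefined
    auc: dict[str, float]  # percent; NaN when undefined
    macro: dict[str, float]  # mean over classes with defined values, percent
    undefined: list[str] = field(default_factory=list)
    n_train: int = 0
    n_test: int = 0

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            return x

        return {
            "tissue": self.tissue,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "subset_width": self.subset_width,
            "confusion": self.confusion.counts.tolist(),
            "class_order": list(self.confusion.class_order),
            "accuracy": clean(round(self.accuracy, 2)),
            "per_class": {
                c: {m: clean(round(v, 2) if not math.isnan(v) else v) for m, v in d.items()}
                for c, d in self.per_class.items()
            },
            "auc": {c: clean(round(v, 2) if not math.isnan(v) else v) for c, v in self.auc.items()},
            "macro": {m: clean(round(v, 2)) for m, v in self.macro.items()},
            "undefined": list(self.undefined),
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def split_dataset(
    patches: Sequence[Patch], spec: SplitSpec
) -> tuple[list[int], list[int]]:
    """Stratified train/test partition over patch indices.

    Per class, ``floor(train_fraction * n)`` shuffled members go to train and
    the remainder to test, so both partitions preserve the class imbalance up
    to rounding.  Classes are processed in canonical order with one seeded
    generator, making the partition deterministic.
    """
    labels = [p.label for p in patches]
    present = [c for c in CLASS_ORDER if c in labels]
    for cls in present:
        if labels.count(cls) < 2:
            raise StratificationError(f"class {cls!r} has fewer than 2 members")
    rng = np.random.default_rng(spec.seed)
    train: list[int] = []
    test: list[int] = []
    for cls in present:
        idx = np.array([i for i, lab in enumerate(labels) if lab == cls])
        rng.shuffle(idx)
        n_train = int(math.floor(spec.train_fraction * len(idx)))
        train.extend(int(i) for i in idx[:n_train])
        test.extend(int(i) for i in idx[n_train:])
    return sorted(train), sorted(test)


class MsvmModel:
    """Fitted multiclass SVM (one-vs-one) with per-class decision scores."""

    def __init__(self, clf: SVC, class_order: tuple[str, ...]):
        self._clf = clf
        self.class_order = class_order

    def predict(self, values: np.ndarray) -> list[str]:
        return [str(v) for v in self._clf.predict(values)]

    def decision_scores(self, values: np.ndarray) -> np.ndarray:
        """(n, K) continuous one-vs-rest scores (aggregated from the
        one-vs-one votes/decision values), columns in ``class_order``."""
        raw = self._clf.decision_function(values)
        if raw.ndim == 1:  # binary problem: one column per class
            raw = np.column_stack([-raw, raw])
        cols = {str(c): j for j, c in enumerate(self._clf.classes_)}
        out = np.full((values.shape[0], len(self.class_order)), np.nan)
        for j, cls in enumerate(self.class_order):
            if cls in cols:
                out[:, j] = raw[:, cols[cls]]
        return out


def train_msvm(
    values: np.ndarray,
    labels: Sequence[str],
    config: SvmConfig = SvmConfig(),
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> MsvmModel:
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] == 0 or values.shape[1] == 0:
        raise ValidationError("training features must be a non-empty 2-D matrix")
    if values.shape[0] != len(labels):
        raise ValidationError("labels length must equal the number of feature rows")
    if len(set(labels)) < 2:
        raise ValidationError("training requires at least two classes")
    clf = SVC(
        kernel=config.kernel,
        C=config.c,
        gamma=config.gamma,
        decision_function_shape="ovr",
    )
    clf.fit(values, list(labels))
    return MsvmModel(clf, class_order)


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("true and predicted label sequences differ in length")
    index = {c: k for k, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValidationError(f"label outside class order: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)


def per_class_metrics(
    cm: ConfusionMatrix,
) -> tuple[dict[str, dict[str, float]], float, list[str]]:
    """One-vs-rest metrics per class (fractions) + overall accuracy.

    Returns ``(per_class, accuracy, undefined)`` where ``undefined`` lists
    ``"metric:class"`` markers for zero-denominator cases (reported as NaN).
    """
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = float(np.trace(c)) / total
    per_class: dict[str, dict[str, float]] = {}
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str, cls: str) -> float:
        if den == 0:
            undefined.append(f"{name}:{cls}")
            return math.nan
        return num / den

    for k, cls in enumerate(cm.class_order):
        tp = float(c[k, k])
        fn = float(c[k, :].sum()) - tp
        fp = float(c[:, k].sum()) - tp
        tn = total - tp - fn - fp
        recall = ratio(tp, tp + fn, "recall", cls)
        specificity = ratio(tn, tn + fp, "specificity", cls)
        precision = ratio(tp, tp + fp, "precision", cls)
        cls_accuracy = (tp + tn) / total
        if math.isnan(recall) or math.isnan(precision) or (precision + recall) == 0:
            undefined.append(f"f1:{cls}")
            f1 = math.nan
        else:
            f1 = 2.0 * precision * recall / (precision + recall)
        per_class[cls] = {
            "recall": recall,
            "specificity": specificity,
            "precision": precision,
            "f1": f1,
            "accuracy": cls_accuracy,
        }
    return per_class, accuracy, undefined


def roc_auc(
    true_labels: Sequence[str],
    scores: np.ndarray,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> dict[str, float]:
    """One-vs-rest AUC per class via the rank-sum (Mann-Whitney) statistic.

    AUC_c = (R_pos - n_pos (n_pos + 1) / 2) / (n_pos * n_neg) where R_pos is
    the rank sum of the class-c scores of class-c samples, average ranks for
    ties (a tied positive/negative pair contributes 1/2).  A class absent
    from the truth (or covering all samples) gets NaN.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(true_labels), len(class_order)):
        raise ValidationError(
            f"scores must have shape (n_samples, {len(class_order)})"
        )
    out: dict[str, float] = {}
    truth = np.asarray(true_labels)
    for k, cls in enumerate(class_order):
        pos = truth == cls
        n_pos = int(pos.sum())
        n_neg = int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[cls] = math.nan
            continue
        ranks = rankdata(scores[:, k])  # average ranks for ties
        r_pos = float(ranks[pos].sum())
        out[cls] = (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return out


def evaluate_split(
    values: np.ndarray,
    labels: Sequence[str],
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    svm_config: SvmConfig = SvmConfig(),
    *,
    tissue: str = "All",
    train_fraction: float = 0.0,
    seed: int = 0,
    subset_width: Optional[int] = None,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> EvalReport:
    """Train on the train rows, evaluate on the test rows, assemble a report.

    All metrics in the report are percentages (0-100), rounded only at
    serialisation time.
    """
    values = np.asarray(values)
    labels = list(labels)
    train_idx = list(train_idx)
    test_idx = list(test_idx)
    model = train_msvm(values[train_idx], [labels[i] for i in train_idx], svm_config, class_order)
    y_true = [labels[i] for i in test_idx]
    y_pred = model.predict(values[test_idx])
    cm = confusion(y_true, y_pred, class_order)
    per_class, accuracy, undefined = per_class_metrics(cm)
    auc = roc_auc(y_true, model.decision_scores(values[test_idx]), class_order)
    for cls, v in auc.items():
        if math.isnan(v):
            undefined.append(f"auc:{cls}")
    per_class_pct = {
        c: {m: v * 100.0 for m, v in d.items()} for c, d in per_class.items()
    }
    auc_pct = {c: v * 100.0 for c, v in auc.items()}
    macro: dict[str, float] = {}
    for metric in ("recall", "specificity", "precision", "f1", "accuracy"):
        vals = [d[metric] for d in per_class_pct.values() if not math.isnan(d[metric])]
        macro[metric] = float(np.mean(vals)) if vals else math.nan
    auc_vals = [v for v in auc_pct.values() if not math.isnan(v)]
    macro["auc"] = float(np.mean(auc_vals)) if auc_vals else math.nan
    return EvalReport(
        tissue=tissue,
        train_fraction=train_fraction,
        seed=seed,
        subset_width=subset_width if subset_width is not None else values.shape[1],
        confusion=cm,
        accuracy=accuracy * 100.0,
        per_class=per_class_pct,
        auc=auc_pct,
        macro=macro,
        undefined=undefined,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )


def aggregate(reports: Sequence[EvalReport], mode: str = "overall") -> pd.DataFrame:
    """Unweighted arithmetic means of report metrics along the chosen axis.

    ``per_tissue`` averages within each tissue subset; ``per_class`` averages
    each class's one-vs-rest metrics across reports; ``overall`` collapses
    everything to a single row.  NaN (undefined) entries are excluded from
    the means.
    """
    if not reports:
        raise ValidationError("aggregate requires at least one report")
    if mode == "per_class":
        rows = []
        for cls in reports[0].confusion.class_order:
            row: dict[str, float] = {"class": cls}
            for metric in ("recall", "specificity", "precision", "f1", "accuracy"):
                row[metric] = float(
                    np.nanmean([r.per_class[cls][metric] for r in reports])
                )
            row["auc"] = float(np.nanmean([r.auc[cls] for r in reports]))
            rows.append(row)
        return pd.DataFrame(rows).set_index("class")
    frame = pd.DataFrame(
        {
            "tissue": r.tissue,
            "train_fraction": r.train_fraction,
            "subset_width": r.subset_width,
            "accuracy": r.accuracy,
            **{f"macro_{m}": v for m, v in r.macro.items()},
        }
        for r in reports
    )
    if mode == "per_tissue":
        return frame.drop(columns=["train_fraction", "subset_width"]).groupby("tissue").mean()
    if mode == "overall":
        return frame.drop(columns=["tissue"]).mean(numeric_only=True).to_frame().T
    raise ValidationError(f"unknown aggregation mode {mode!r}")
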