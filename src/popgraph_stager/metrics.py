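"""Confusion matrices and classification metrics (percent scale).

Binary reports carry accuracy, precision, recall, F1 (harmonic mean of
precision and recall) and the Matthews correlation coefficient with the
standard square-rooted denominator

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)).

Ratios with a zero denominator are reported as 0 and flagged.  A linear
support-vector baseline reproduces the graph-versus-vector comparison on
plain feature matrices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, columns = predicted
    class_order: list
    positive_class: object | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape must match class_order")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.positive_class is not None \
                and self.positive_class not in self.class_order:
            raise ValueError("positive_class not in class_order")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=pd.Index(self.class_order, name="true"),
                            columns=pd.Index(self.class_order, name="predicted"))


@dataclass
class MetricsReport:
    acc: float
    pre: float
    rec: float
    f1: float
    mcc: float
    undefined: list[str] = field(default_factory=list)

    def as_row(self) -> dict[str, float]:
        return {"ACC": self.acc, "PRE": self.pre, "REC": self.rec,
                "F1": self.f1, "MCC": self.mcc}


def confusion(y_true, y_pred, class_order) -> ConfusionMatrix:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    unknown = (set(y_true) | set(y_pred)) - set(index)
    if unknown:
        raise ValueError(f"labels outside class_order: {sorted(map(str, unknown))}")
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=list(class_order))


def _safe_ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def binary_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """ACC/PRE/REC/F1/MCC from a 2x2 confusion matrix, in percent."""
    if cm.counts.shape != (2, 2):
        raise ValueError("binary metrics need a 2x2 confusion matrix")
    pos = cm.positive_class if cm.positive_class is not None \
        else cm.class_order[1]
    p = cm.class_order.index(pos)
    n = 1 - p
    tp = int(cm.counts[p, p])
    fn = int(cm.counts[p, n])
    fp = int(cm.counts[n, p])
    tn = int(cm.counts[n, n])
    flags: list[str] = []
    acc = _safe_ratio(tp + tn, tp + tn + fp + fn, "acc", flags)
    pre = _safe_ratio(tp, tp + fp, "pre", flags)
    rec = _safe_ratio(tp, tp + fn, "rec", flags)
    f1 = _safe_ratio(2 * pre * rec, pre + rec, "f1", flags)
    den = np.sqrt(float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    mcc = _safe_ratio(tp * tn - fp * fn, den, "mcc", flags)
    return MetricsReport(acc=100 * acc, pre=100 * pre, rec=100 * rec,
                         f1=100 * f1, mcc=100 * mcc, undefined=flags)


def multiclass_metrics(cm: ConfusionMatrix) -> tuple[float, pd.DataFrame]:
    """Overall accuracy plus one-vs-rest precision/recall per class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    overall = 100.0 * np.trace(cm.counts) / cm.total
    rows = []
    for i, cls in enumerate(cm.class_order):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i].sum() - tp)
        fp = int(cm.counts[:, i].sum() - tp)
        flags: list[str] = []
        rows.append({
            "class": cls,
            "precision": 100 * _safe_ratio(tp, tp + fp, "pre", flags),
            "recall": 100 * _safe_ratio(tp, tp + fn, "rec", flags),
            "support": tp + fn,
        })
    return overall, pd.DataFrame(rows)


def f1_from_pre_rec(pre: float, rec: float) -> float:
    """Harmonic mean of precision and recall (same scale as the inputs)."""
    if pre + rec == 0:
        return 0.0
    return 2.0 * pre * rec / (pre + rec)


def vector_baseline(
    X: np.ndarray,
    labels: np.ndarray,
    masks: dict[str, np.ndarray],
    positive_class: int | None = None,
    seed: int = 0,
) -> tuple[MetricsReport, np.ndarray]:
    """Linear SVM on raw (vector) features: the non-graph comparison arm.

    Trains on the train mask and reports test-mask metrics; 1-D score inputs
    are accepted as a column.  Returns the report and the test predictions.
    """
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels, int)
    train, test = masks["train"], masks["test"]
    if len(set(labels[train].tolist())) < 2:
        raise ValueError("training data contains a single class")
    scaler = StandardScaler().fit(X[train])
    clf = SVC(kernel="linear", random_state=seed)
    clf.fit(scaler.transform(X[train]), labels[train])
    pred = clf.predict(scaler.transform(X[test]))
    classes = sorted(set(labels.tolist()))
    cm = confusion(labels[test], pred, classes)
    if len(classes) == 2:
        cm.positive_class = positive_class if positive_class is not None \
            else classes[1]
        return binary_metrics(cm), pred
    overall, _ = multiclass_metrics(cm)
    return MetricsReport(acc=overall, pre=float("nan"), rec=float("nan"),
                         f1=float("nan"), mcc=float("nan")), pred


def report_table_to_csv(table: pd.DataFrame, path) -> None:
    """Results rows in the ACC/PRE/REC/F1/MCC column order, one decimal."""
    table.to_csv(path, index=False, float_format="%.1f")
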