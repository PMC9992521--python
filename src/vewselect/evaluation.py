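"""External evaluation of a selected gene subset.

Tenfold stratified cross-validation with decision-tree (DT), support-vector
(SVM) and logistic-regression (LR) classifiers, scored with accuracy and
macro-averaged precision / recall / F1:

    Acc = (TP + TN) / (P + N)          Precision = TP / (TP + FP)
    Recall = TP / (TP + FN)            F1 = 2 * Pre * Rec / (Pre + Rec)

Per-class values use one-vs-rest confusion counts; macro averages give each
class equal weight. Zero denominators yield 0 for that class's metric —
with tiny test folds an empty predicted-positive set is routine, and 0 is
the conservative convention. Repeated independent runs are aggregated as
mean and sample standard deviation per metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datasets import ExpressionDataset
from .errors import EmptySelectionError
from .filters import GeneSubset

METRIC_NAMES = ("acc", "precision", "recall", "f1")
CLASSIFIERS = ("dt", "svm", "lr")


def make_classifier(name: str, seed: int = 0):
    """Factory for the external classifiers (library defaults, logged by callers)."""
    name = name.lower()
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if name == "svm":
        return SVC(random_state=seed)
    if name == "lr":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts per class.

    ``matrix[i, j]`` counts samples of true class ``classes[i]`` predicted as
    ``classes[j]``. For each class c: TP = matrix[c, c], FP = column sum - TP,
    FN = row sum - TP, TN = remainder; TP+TN+FP+FN equals the sample total
    for every class.
    """

    classes: tuple
    matrix: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def per_class(self) -> dict:
        out = {}
        total = self.total
        for i, c in enumerate(self.classes):
            tp = int(self.matrix[i, i])
            fp = int(self.matrix[:, i].sum()) - tp
            fn = int(self.matrix[i, :].sum()) - tp
            out[c] = {"TP": tp, "FP": fp, "FN": fn, "TN": total - tp - fp - fn}
        return out

    def binary_view(self, positive=None) -> dict:
        """TP/TN/FP/FN (plus P, N totals) for a designated positive class."""
        if self.n_classes != 2 and positive is None:
            raise ValueError("positive class required for non-binary data")
        if positive is None:
            positive = self.classes[-1]
        counts = self.per_class()[positive]
        return {**counts, "P": counts["TP"] + counts["FN"],
                "N": counts["TN"] + counts["FP"]}


def confusion_counts(true_labels, predicted_labels, classes=None) -> ConfusionCounts:
    """Tally a confusion matrix over a shared, sorted class set."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    if classes is None:
        cls = np.unique(np.concatenate([y_true, y_pred]))
    else:
        cls = np.asarray(classes)
        known = set(cls.tolist())
        stray = {l for l in np.concatenate([y_true, y_pred]).tolist() if l not in known}
        if stray:
            raise ValueError(f"labels outside the known class set: {sorted(map(str, stray))}")
    index = {c: i for i, c in enumerate(cls.tolist())}
    matrix = np.zeros((cls.size, cls.size), dtype=int)
    for t, p in zip(y_true.tolist(), y_pred.tolist()):
        matrix[index[t], index[p]] += 1
    return ConfusionCounts(tuple(cls.tolist()), matrix)


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy plus macro precision/recall/F1 and the per-class breakdown."""

    acc: float
    precision: float
    recall: float
    f1: float
    per_class: dict = field(default_factory=dict)
    classifier: str | None = None

    def as_dict(self) -> dict:
        return {"acc": self.acc, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(cc: ConfusionCounts, classifier: str | None = None) -> MetricsReport:
    """Accuracy and equal-weight (macro) precision/recall/F1 from confusion counts."""
    acc = _safe_div(float(np.trace(cc.matrix)), float(cc.total))
    per_class = {}
    for c, counts in cc.per_class().items():
        pre = _safe_div(counts["TP"], counts["TP"] + counts["FP"])
        rec = _safe_div(counts["TP"], counts["TP"] + counts["FN"])
        f1 = _safe_div(2.0 * pre * rec, pre + rec)
        per_class[c] = {"precision": pre, "recall": rec, "f1": f1}
    return MetricsReport(
        acc=acc,
        precision=float(np.mean([v["precision"] for v in per_class.values()])),
        recall=float(np.mean([v["recall"] for v in per_class.values()])),
        f1=float(np.mean([v["f1"] for v in per_class.values()])),
        per_class=per_class,
        classifier=classifier,
    )


@dataclass(frozen=True)
class CVReport:
    """Per-fold metrics with their mean, and (after aggregation) cross-run SD."""

    classifier: str
    n_folds: int
    fold_metrics: tuple[MetricsReport, ...]
    metric_means: dict
    metric_sds: dict

    @property
    def mean_acc(self) -> float:
        return self.metric_means["acc"]


def crossval_evaluate(
    ds: ExpressionDataset,
    subset: GeneSubset,
    classifier: str = "svm",
    folds: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold evaluation of one classifier on the subset's genes.

    If the smallest class has fewer samples than ``folds`` the fold count is
    reduced (with a warning) — small classes are the norm in
    high-dimension/low-sample expression data.
    """
    if len(subset) == 0:
        raise EmptySelectionError("cannot evaluate an empty gene subset")
    X = subset.restrict(ds.values)
    y = ds.labels
    _, class_counts = np.unique(y, return_counts=True)
    min_class = int(class_counts.min())
    eff_folds = folds
    if min_class < folds:
        eff_folds = max(2, min_class)
        warnings.warn(
            f"folds reduced {folds} -> {eff_folds}: smallest class has "
            f"{min_class} samples",
            stacklevel=2,
        )
    splitter = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    classes = tuple(np.unique(y).tolist())
    fold_metrics = []
    for train, test in splitter.split(X, y):
        clf = make_classifier(classifier, seed=seed)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        cc = confusion_counts(y[test], pred, classes=classes)
        fold_metrics.append(compute_metrics(cc, classifier=classifier))
    means = {m: float(np.mean([fm.as_dict()[m] for fm in fold_metrics]))
             for m in METRIC_NAMES}
    return CVReport(
        classifier=classifier,
        n_folds=eff_folds,
        fold_metrics=tuple(fold_metrics),
        metric_means=means,
        metric_sds={m: 0.0 for m in METRIC_NAMES},
    )


def aggregate_runs(reports: list[CVReport]) -> CVReport:
    """Cross-run mean and sample SD per metric over independent repetitions."""
    if not reports:
        raise ValueError("no reports to aggregate")
    tags = {r.classifier for r in reports}
    if len(tags) != 1:
        raise ValueError(f"mixed classifiers in aggregation: {sorted(tags)}")
    means, sds = {}, {}
    for m in METRIC_NAMES:
        vals = np.array([r.metric_means[m] for r in reports])
        means[m] = float(vals.mean())
        sds[m] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return CVReport(
        classifier=reports[0].classifier,
        n_folds=reports[0].n_folds,
        fold_metrics=(),
        metric_means=means,
        metric_sds=sds,
    )
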