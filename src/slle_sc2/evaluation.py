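"""Classification-based evaluation of selected gene sets.

Confusion-matrix metrics (accuracy, TPR, TNR, precision, F-measure, G-mean),
rank-statistic AUC, stratified k-fold cross-validation with gene selection
re-fit inside every training fold, and the correlation-threshold sweep.
Classifiers are delegated to scikit-learn behind a small registry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core_manifold import LabeledExpressionMatrix
from .errors import DataValidationError, ParameterError
from .selection_pipeline import slle_sc2_select

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVReport",
    "confusion_metrics",
    "auc",
    "cross_validate",
    "threshold_sweep",
    "make_classifier",
    "CLASSIFIERS",
]

METRIC_NAMES = ("acc", "tpr", "tnr", "precision", "f_measure", "g_mean", "auc")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    acc: float
    tpr: float
    tnr: float
    precision: float
    f_measure: float
    g_mean: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class CVReport:
    folds: list[MetricSet]
    mean: dict
    std: dict
    selected_per_fold: list[list[str]]
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.folds]
        return pd.DataFrame(rows)


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, TPR, TNR, precision, F-measure and G-mean from counts.

    Precision (and hence F-measure) is defined as 0 when no sample is
    predicted positive.
    """
    if c.tp + c.fn == 0:
        raise DataValidationError("no positive samples in the evaluated set")
    if c.tn + c.fp == 0:
        raise DataValidationError("no negative samples in the evaluated set")
    acc = (c.tp + c.tn) / c.total
    tpr = c.tp / (c.tp + c.fn)
    tnr = c.tn / (c.tn + c.fp)
    if c.tp + c.fp == 0:
        warnings.warn("no predicted positives: precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    f = 0.0 if precision + tpr == 0 else 2 * precision * tpr / (precision + tpr)
    g = math.sqrt(tpr * tnr)
    return MetricSet(acc=acc, tpr=tpr, tnr=tnr, precision=precision, f_measure=f, g_mean=g)


def auc(labels: Sequence | np.ndarray, scores: Sequence[float] | np.ndarray,
        positive_label=None) -> float:
    """Area under the ROC curve via the tie-corrected rank statistic.

    Equals (concordant + 0.5 * tied) / (n_pos * n_neg), which is the
    trapezoidal area under the ROC curve.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise DataValidationError("labels and scores must align")
    if not np.all(np.isfinite(scores)):
        raise DataValidationError("scores contain non-finite values")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise DataValidationError(f"AUC needs exactly 2 classes, got {len(classes)}")
    if positive_label is None:
        positive_label = classes[-1]  # lexicographically greater
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    r = rankdata(scores, method="average")
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


CLASSIFIERS = ("svm", "c45", "naive_bayes", "knn")


def make_classifier(name: str, seed: int | None = None):
    """scikit-learn estimator for a classifier name; defaults are recorded upstream."""
    if name == "svm":
        return SVC(random_state=seed)
    if name == "c45":
        # entropy criterion is the closest stock analogue of C4.5
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "knn":
        return KNeighborsClassifier()
    raise ParameterError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _scores(clf, x: np.ndarray, positive_index: int) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        s = clf.decision_function(x)
        # decision_function is signed towards classes_[-1]
        if positive_index == 0:
            s = -s
        return s
    return clf.predict_proba(x)[:, positive_index]


def _positive_label(labels: np.ndarray, positive_label=None):
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise DataValidationError("binary labels required")
    if positive_label is None:
        positive_label = classes[-1]
        warnings.warn(
            f"positive label not given: using {positive_label!r} "
            "(lexicographically greater)",
            stacklevel=3,
        )
    elif positive_label not in classes:
        raise ParameterError(f"positive label {positive_label!r} not in data")
    return positive_label


def cross_validate(
    x: LabeledExpressionMatrix,
    selector: dict | None = None,
    classifier: str = "svm",
    folds: int = 10,
    repeats: int = 2,
    seed: int = 0,
    positive_label=None,
) -> CVReport:
    """Stratified k-fold cross-validation with selection nested inside folds.

    ``selector`` is a keyword dict for :func:`slle_sc2_select` applied to the
    TRAINING portion of each fold only (pass ``None`` to use every gene).
    Metrics are collected per held-out fold across ``repeats`` shuffles.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    labels = np.asarray(x.labels)
    pos = _positive_label(labels, positive_label)
    y = (labels == pos).astype(int)
    if y.sum() < folds or (len(y) - y.sum()) < folds:
        raise DataValidationError(
            "a class has fewer samples than folds: stratification impossible"
        )

    fold_metrics: list[MetricSet] = []
    selected_per_fold: list[list[str]] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for train_idx, test_idx in skf.split(x.values, y):
            if selector is None:
                genes = list(x.gene_ids)
            else:
                x_train = LabeledExpressionMatrix(
                    values=x.values[train_idx],
                    gene_ids=list(x.gene_ids),
                    sample_ids=[x.sample_ids[i] for i in train_idx],
                    labels=labels[train_idx],
                )
                genes = slle_sc2_select(x_train, seed=seed, **selector).selected
            cols = [x.gene_ids.index(g) for g in genes]
            clf = make_classifier(classifier, seed=seed)
            clf.fit(x.values[np.ix_(train_idx, cols)], labels[train_idx])
            xt = x.values[np.ix_(test_idx, cols)]
            pred = clf.predict(xt)
            truth = labels[test_idx]
            counts = ConfusionCounts(
                tp=int(np.sum((pred == pos) & (truth == pos))),
                tn=int(np.sum((pred != pos) & (truth != pos))),
                fp=int(np.sum((pred == pos) & (truth != pos))),
                fn=int(np.sum((pred != pos) & (truth == pos))),
            )
            ms = confusion_metrics(counts)
            pos_index = int(np.nonzero(clf.classes_ == pos)[0][0])
            ms.auc = auc(truth, _scores(clf, xt, pos_index), positive_label=pos)
            fold_metrics.append(ms)
            selected_per_fold.append(genes)

    frame = pd.DataFrame([m.as_dict() for m in fold_metrics])
    return CVReport(
        folds=fold_metrics,
        mean=frame.mean().to_dict(),
        std=frame.std(ddof=1).to_dict(),
        selected_per_fold=selected_per_fold,
        params={
            "selector": selector,
            "classifier": classifier,
            "folds": folds,
            "repeats": repeats,
            "positive_label": pos,
        },
        seed=seed,
    )


def threshold_sweep(
    x: LabeledExpressionMatrix,
    thresholds: Sequence[float] | None = None,
    selector: dict | None = None,
    classifier: str = "svm",
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    positive_label=None,
) -> pd.DataFrame:
    """CV accuracy and surviving-gene count per redundancy threshold.

    Returns a table with one row per threshold (default grid 0.0..1.0 in
    steps of 0.1): mean accuracy across folds and the mean number of genes
    selected inside the folds.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    base = dict(selector or {})
    rows = []
    for t in thresholds:
        cfg = {**base, "threshold": float(t)}
        report = cross_validate(
            x,
            selector=cfg,
            classifier=classifier,
            folds=folds,
            repeats=repeats,
            seed=seed,
            positive_label=positive_label,
        )
        n_sel = float(np.mean([len(g) for g in report.selected_per_fold]))
        rows.append(
            {"threshold": float(t), "mean_accuracy": report.mean["acc"], "n_selected": n_sel}
        )
    return pd.DataFrame(rows)
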