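"""SVM classification of tumor vs normal samples and evaluation metrics.

The positive class is tumor (label 1).  From the 2x2 confusion tally
(tpv, fpv, fnv, tnv):

    precision   = tpv / (tpv + fpv)
    recall      = tpv / (tpv + fnv)        (sensitivity, TPR)
    F-measure   = 2 * Pr * Re / (Pr + Re)
    specificity = tnv / (tnv + fpv)
    accuracy    = (tpv + tnv) / total

ROC points tabulate (FPR, TPR) across score thresholds; the mean TPR over
the tabulated operating points summarises a ROC table, and a trapezoidal
AUC is also provided.  `cross_validate` runs stratified k-fold with gene
selection nested inside each training fold so no information leaks from
the held-out samples into the selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import ExpressionMatrix

__all__ = [
    "ConfusionCounts",
    "ClassificationReport",
    "SvmModel",
    "train_svm",
    "confusion_counts",
    "metrics_report",
    "roc_table",
    "mean_tpr",
    "trapezoid_auc",
    "compare_reports",
    "report_from_percent_metrics",
    "cross_validate",
]

METRIC_NAMES = ("precision", "recall", "f_measure", "specificity", "accuracy")


@dataclass
class ConfusionCounts:
    tpv: int
    fpv: int
    fnv: int
    tnv: int

    @property
    def total(self) -> int:
        return self.tpv + self.fpv + self.fnv + self.tnv

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tpv + other.tpv, self.fpv + other.fpv,
                               self.fnv + other.fnv, self.tnv + other.tnv)


@dataclass
class ClassificationReport:
    """Proportion-valued metrics plus optional ROC summaries.

    Undefined metrics (zero denominator) are None and listed in
    ``undefined`` rather than silently reported as 0.
    """

    precision: float | None
    recall: float | None
    f_measure: float | None
    specificity: float | None
    accuracy: float | None
    undefined: tuple[str, ...] = ()
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    mean_tpr: float | None = None
    auc: float | None = None
    counts: ConfusionCounts | None = None

    def as_percent(self) -> dict[str, float | None]:
        """Metrics as percentages rounded to two decimals."""
        return {
            name: (None if getattr(self, name) is None
                   else round(100 * getattr(self, name), 2))
            for name in METRIC_NAMES
        }


@dataclass
class SvmModel:
    """Fitted binary SVM over a fixed gene panel (genes x samples input)."""

    estimator: SVC
    gene_ids: list[str] | None = None

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float).T)

    def decision_score(self, X) -> np.ndarray:
        return self.estimator.decision_function(np.asarray(X, dtype=float).T)


def train_svm(
    X_selected,
    y: np.ndarray,
    kernel: str = "rbf",
    C: float = 1.0,
    seed: int = 0,
) -> SvmModel:
    """Fit a binary SVM on a genes x samples matrix of selected genes."""
    if isinstance(X_selected, ExpressionMatrix):
        gene_ids, G = X_selected.gene_ids, X_selected.values
    else:
        gene_ids, G = None, np.asarray(X_selected, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    est = SVC(kernel=kernel, C=C, random_state=seed)
    est.fit(G.T, y)
    return SvmModel(estimator=est, gene_ids=gene_ids)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """2x2 tally with tumor (1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    return ConfusionCounts(
        tpv=int(((y_true == 1) & (y_pred == 1)).sum()),
        fpv=int(((y_true == 0) & (y_pred == 1)).sum()),
        fnv=int(((y_true == 1) & (y_pred == 0)).sum()),
        tnv=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics_report(c: ConfusionCounts) -> ClassificationReport:
    """Scalar metrics from confusion counts; zero denominators are flagged."""
    pr = _ratio(c.tpv, c.tpv + c.fpv)
    re = _ratio(c.tpv, c.tpv + c.fnv)
    sp = _ratio(c.tnv, c.tnv + c.fpv)
    acc = _ratio(c.tpv + c.tnv, c.total)
    if pr is None or re is None or (pr + re) == 0:
        fm = None
    else:
        fm = 2 * pr * re / (pr + re)
    undefined = tuple(
        name for name, v in zip(
            METRIC_NAMES, (pr, re, fm, sp, acc)) if v is None
    )
    return ClassificationReport(precision=pr, recall=re, f_measure=fm,
                                specificity=sp, accuracy=acc,
                                undefined=undefined, counts=c)


def roc_table(
    scores,
    y_true,
    thresholds=None,
) -> list[tuple[float, float]]:
    """(FPR, TPR) per threshold; prediction is positive when score > t.

    Default thresholds bracket the unique scores, so the table runs from
    (0, 0) (threshold above all scores) to (1, 1).  Sorted by FPR then
    TPR.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes present")
    if thresholds is None:
        uniq = np.unique(scores)
        thresholds = np.concatenate(([uniq[0] - 1.0], uniq))
    pos = (y_true == 1).sum()
    neg = (y_true == 0).sum()
    points = []
    for t in np.asarray(thresholds, dtype=float):
        pred = scores > t
        tpr = (pred & (y_true == 1)).sum() / pos
        fpr = (pred & (y_true == 0)).sum() / neg
        points.append((float(fpr), float(tpr)))
    return sorted(points)


def mean_tpr(roc_points) -> float:
    """Arithmetic mean of the tabulated TPR values."""
    points = list(roc_points)
    if not points:
        raise ValueError("empty ROC table")
    return float(np.mean([tpr for _, tpr in points]))


def trapezoid_auc(roc_points) -> float:
    """Trapezoidal area under the tabulated ROC points (anchored at 0,0/1,1)."""
    pts = sorted(set(roc_points) | {(0.0, 0.0), (1.0, 1.0)})
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def report_from_percent_metrics(
    precision: float, recall: float, f_measure: float,
    specificity: float, accuracy: float,
) -> ClassificationReport:
    """Build a report from published percentage metrics (e.g. a results table)."""
    return ClassificationReport(
        precision=precision / 100, recall=recall / 100,
        f_measure=f_measure / 100, specificity=specificity / 100,
        accuracy=accuracy / 100,
    )


def compare_reports(
    reports: dict[str, ClassificationReport],
    reference: str | None = None,
) -> pd.DataFrame:
    """Pairwise metric differences (reference - other) in percentage points.

    Rows are metrics, columns the non-reference methods; values rounded to
    two decimals.  The reference defaults to the first name.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    names = list(reports)
    ref = names[0] if reference is None else reference
    if ref not in reports:
        raise KeyError(f"unknown reference {ref!r}")
    others = [n for n in names if n != ref]
    table = {}
    for other in others:
        col = {}
        for metric in METRIC_NAMES:
            a = getattr(reports[ref], metric)
            b = getattr(reports[other], metric)
            col[metric] = (None if a is None or b is None
                           else round(100 * (a - b), 2))
        table[other] = col
    return pd.DataFrame(table).reindex(METRIC_NAMES)


def cross_validate(
    X,
    y: np.ndarray,
    selector=None,
    kernel: str = "rbf",
    C: float = 1.0,
    folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold CV with selection nested inside training folds.

    ``selector`` is a callable ``(X_train, y_train, fold_seed) -> boolean
    gene mask`` applied to each training fold only; None uses all genes.
    Confusion counts are pooled across folds into a single report; ROC
    summaries come from the pooled decision scores.
    """
    G = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds with a class of size {class_counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    all_scores = np.empty_like(y, dtype=float)
    for fold, (tr, te) in enumerate(skf.split(G.T, y)):
        Gtr, Gte = G[:, tr], G[:, te]
        if selector is None:
            mask = np.ones(G.shape[0], dtype=bool)
        else:
            mask = np.asarray(selector(Gtr, y[tr], seed + fold), dtype=bool)
        model = train_svm(Gtr[mask], y[tr], kernel=kernel, C=C, seed=seed)
        pred = model.predict(Gte[mask])
        all_scores[te] = model.decision_score(Gte[mask])
        pooled = pooled + confusion_counts(y[te], pred)
    report = metrics_report(pooled)
    points = roc_table(all_scores, y)
    report.roc_points = points
    report.mean_tpr = mean_tpr(points)
    report.auc = trapezoid_auc(points)
    return report
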