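"""Classification metrics, ROC/PR curves, and (nested) cross-validation.

Scalar metrics follow the standard confusion-matrix definitions with
class 1 (ACP) as the positive class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Ratios with a zero denominator are reported as 0 and flagged rather than
raising, so degenerate folds never abort a cross-validation sweep.

AUROC uses the trapezoidal rule over the ROC curve; AUPRC uses the
step-wise (interpolation-free) convention, i.e. average precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .cascade import CascadeConfig, CascadeForest


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts with class 1 = positive (ACP)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Scalar metrics plus optional threshold-sweep curves and AUCs."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()   # metrics whose denominator was zero
    auroc: float | None = None
    auprc: float | None = None
    roc_points: np.ndarray | None = None  # (t, 2): FPR, TPR
    pr_points: np.ndarray | None = None   # (t, 2): recall, precision

    def scalars(self) -> dict[str, float]:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }
        if self.auroc is not None:
            out["auroc"] = self.auroc
        if self.auprc is not None:
            out["auprc"] = self.auprc
        return out


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValueError("labels and predictions must be equal-length 1-D, non-empty")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Scalar metrics from confusion counts (see module docstring)."""
    if counts.total == 0:
        raise ValueError("no samples")
    undefined: list[str] = []
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = _safe_div(counts.tp, counts.tp + counts.fp, "precision", undefined)
    recall = _safe_div(counts.tp, counts.tp + counts.fn, "recall", undefined)
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1", undefined)
    return MetricsReport(
        counts=counts,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        undefined=tuple(undefined),
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 if both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def roc_pr(y_true, scores) -> MetricsReport:
    """ROC and PR curves with areas, from ACP-probability scores.

    Requires both classes present.  AUROC is trapezoidal; AUPRC is the
    step-wise average-precision convention.  Scalar metrics in the returned
    report use the 0.5 threshold.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size != 2:
        raise ValueError("ROC/PR need both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores)
    auroc = float(auc(fpr, tpr))
    prec, rec, _ = precision_recall_curve(y_true, scores)
    auprc = float(average_precision_score(y_true, scores))
    base = metrics(confusion(y_true, (scores >= 0.5).astype(int)))
    return replace(
        base,
        auroc=auroc,
        auprc=auprc,
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec, prec]),
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold metrics and their mean for one configuration."""

    fold_reports: list[MetricsReport]
    mean: dict[str, float]
    config: CascadeConfig


def cross_validate(
    X,
    y,
    config: CascadeConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    model_factory=None,
) -> CVResult:
    """Seeded stratified k-fold cross-validation of the cascade.

    ``model_factory(config, fold_seed)`` may override the estimator (it
    must expose fit/predict/predict_proba); by default a
    :class:`CascadeForest` is trained per fold with a fold-derived seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    config = config or CascadeConfig()
    if len(y) < folds:
        raise ValueError(f"{len(y)} samples cannot fill {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        fold_seed = (seed * 1000 + fold_i) % (2**31 - 1)
        if model_factory is not None:
            model = model_factory(config, fold_seed)
        else:
            model = CascadeForest(config=replace(config, seed=fold_seed))
        model.fit(X[train_idx], y[train_idx])
        scores = model.predict_proba(X[test_idx])[:, 1]
        reports.append(roc_pr(y[test_idx], scores))
    keys = reports[0].scalars().keys()
    mean = {k: float(np.mean([r.scalars()[k] for r in reports])) for k in keys}
    return CVResult(fold_reports=reports, mean=mean, config=config)


def grid_search_n(
    X,
    y,
    config: CascadeConfig | None = None,
    grid: tuple[int, ...] = (1, 2, 4),
    folds: int = 5,
    seed: int = 0,
    criterion: str = "accuracy",
) -> tuple[int, dict[int, float]]:
    """Select forests-per-type ``n`` by k-fold CV mean accuracy (or F1).

    Ties resolve to the smaller ``n``.
    """
    config = config or CascadeConfig()
    scores: dict[int, float] = {}
    for n in grid:
        result = cross_validate(X, y, replace(config, n_forests=n), folds=folds, seed=seed)
        scores[n] = result.mean[criterion]
    best = max(sorted(scores), key=lambda n: scores[n])  # sorted => tie -> smaller n
    return best, scores


@dataclass
class NestedCVResult:
    """Outer-fold reports, the n chosen per outer fold, and mean metrics."""

    outer_reports: list[MetricsReport]
    chosen_n: list[int]
    mean: dict[str, float]


def nested_cv(
    X,
    y,
    config: CascadeConfig | None = None,
    outer: int = 5,
    inner: int = 5,
    seed: int = 0,
    grid: tuple[int, ...] = (1, 2, 4),
    criterion: str = "accuracy",
) -> NestedCVResult:
    """Nested cross-validation: inner folds select ``n``, outer folds test.

    For each outer fold the hyperparameter is chosen by ``inner``-fold CV
    on the outer-training part only, the cascade is refitted on that part,
    and evaluated once on the held-out outer-test part.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    config = config or CascadeConfig()
    skf = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    chosen: list[int] = []
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        fold_seed = (seed * 1000 + fold_i) % (2**31 - 1)
        best_n, _ = grid_search_n(
            X[train_idx], y[train_idx], config, grid=grid, folds=inner,
            seed=fold_seed, criterion=criterion,
        )
        chosen.append(best_n)
        model = CascadeForest(config=replace(config, n_forests=best_n, seed=fold_seed))
        model.fit(X[train_idx], y[train_idx])
        scores = model.predict_proba(X[test_idx])[:, 1]
        reports.append(roc_pr(y[test_idx], scores))
    keys = reports[0].scalars().keys()
    mean = {k: float(np.mean([r.scalars()[k] for r in reports])) for k in keys}
    return NestedCVResult(outer_reports=reports, chosen_n=chosen, mean=mean)


def plot_roc_pr(report: MetricsReport, path) -> None:
    """Write a two-panel ROC / PR figure for one evaluated model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.roc_points is None or report.pr_points is None:
        raise ValueError("report has no curves; use roc_pr() with scores")
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(report.roc_points[:, 0], report.roc_points[:, 1],
             label=f"AUROC = {report.auroc:.3f}")
    ax1.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax1.set_xlabel("False positive rate")
    ax1.set_ylabel("True positive rate")
    ax1.set_title("ROC")
    ax1.legend()
    ax2.plot(report.pr_points[:, 0], report.pr_points[:, 1],
             label=f"AUPRC = {report.auprc:.3f}")
    ax2.set_xlabel("Recall")
    ax2.set_ylabel("Precision")
    ax2.set_title("Precision-Recall")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
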