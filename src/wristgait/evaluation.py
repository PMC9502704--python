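"""Imbalance-aware evaluation: confusion-matrix metrics, ROC and PR curves
with trapezoid AUCs, threshold application, and cross-validated aggregation
(mean +/- STD over folds).

Accuracy, specificity, sensitivity (recall) and precision are reported in
percent. Under the heavy gait/non-gait imbalance of daily-living data the
ROC curve is optimistic, so the precision-recall curve and its AUC are
reported alongside; balanced accuracy (mean of sensitivity and specificity)
is exported for comparability with wrist-detection literature. Metrics with
zero denominators are flagged undefined and excluded from fold means with a
warning rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve as _sk_pr
from sklearn.metrics import roc_curve as _sk_roc

__all__ = [
    "ConfusionCounts", "CurveResult", "FoldReport",
    "confusion", "metrics", "balanced_accuracy", "roc_pr_curves",
    "apply_threshold", "crossval_report",
]

HIGH_PRECISION_THRESHOLD = 0.9


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, specificity, sensitivity, precision in percent; metrics
    with a zero denominator come back as NaN (flagged undefined)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "accuracy": pct(c.tp + c.tn, c.total),
        "specificity": pct(c.tn, c.tn + c.fp),
        "sensitivity": pct(c.tp, c.tp + c.fn),
        "precision": pct(c.tp, c.tp + c.fp),
    }


def balanced_accuracy(c: ConfusionCounts) -> float:
    m = metrics(c)
    return (m["sensitivity"] + m["specificity"]) / 2.0


@dataclass
class CurveResult:
    """Ordered curve points with trapezoid AUC.

    ROC: x = false positive rate, y = true positive rate (starts (0,0),
    ends (1,1)). PR: x = recall, y = precision over achieved points.
    """

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    auc: float
    kind: str

    def as_frame(self) -> pd.DataFrame:
        n = len(self.x)
        th = np.full(n, np.nan)
        th[: len(self.thresholds)] = self.thresholds[:n]
        return pd.DataFrame({"threshold": th, "x": self.x, "y": self.y})


def roc_pr_curves(scores: Sequence[float], truth: Sequence[int]
                  ) -> tuple[CurveResult, CurveResult]:
    """ROC and PR curves over all distinct score thresholds (equal scores
    grouped into one step); AUCs by trapezoid over the achieved points."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if truth.min() == truth.max():
        raise ValueError("truth must contain both classes")
    fpr, tpr, roc_th = _sk_roc(truth, scores, drop_intermediate=False)
    roc_auc = float(np.trapezoid(tpr, fpr))
    prec, rec, pr_th = _sk_pr(truth, scores)
    # integrate along the threshold-ordered path (recall 0 -> 1, anchored at
    # the (recall 0, precision 1) endpoint); vertical precision drops at
    # repeated recall values contribute zero width
    rec_o, prec_o = rec[::-1], prec[::-1]
    pr_auc = float(np.trapezoid(prec_o, rec_o))
    roc = CurveResult(x=fpr, y=tpr, thresholds=roc_th, auc=roc_auc, kind="roc")
    pr = CurveResult(x=rec_o, y=prec_o, thresholds=pr_th[::-1], auc=pr_auc,
                     kind="pr")
    return roc, pr


def apply_threshold(probs: Sequence[float],
                    threshold: float = HIGH_PRECISION_THRESHOLD) -> np.ndarray:
    """Binary prediction: positive iff probability > threshold."""
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs > threshold).astype(np.int8)


@dataclass
class FoldReport:
    """Per-fold metric values with mean and across-fold STD."""

    per_fold: pd.DataFrame              # rows = folds, columns = metrics
    fold_assignment: dict[str, int] = field(default_factory=dict)

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean(skipna=True)

    @property
    def std(self) -> pd.Series:
        if len(self.per_fold) < 2:
            raise ValueError("fold STD requires >= 2 folds")
        return self.per_fold.std(ddof=1, skipna=True)

    def summary(self) -> pd.DataFrame:
        if self.per_fold.isna().any().any():
            warnings.warn("undefined metrics excluded from fold means")
        return pd.DataFrame({"mean": self.mean, "std": self.std})

    def formatted(self) -> pd.Series:
        s = self.summary()
        return s.apply(
            lambda r: "" if pd.isna(r["mean"])
            else f"{r['mean']:.1f} ({r['std']:.1f})", axis=1)


def crossval_report(
    recordings: Sequence,
    detector_run: Callable,
    folds,
    threshold: float = HIGH_PRECISION_THRESHOLD,
    continuous: bool = True,
) -> FoldReport:
    """Subject-disjoint cross-validation driver.

    ``detector_run(train_recs, test_recs)`` must return ``(probs, truth)``
    aligned 1-d arrays for the held-out recordings (window- or
    sample-level). Each fold trains on the other k-1 folds; the four
    confusion metrics at ``threshold``, balanced accuracy and (where both
    classes appear) ROC/PR AUCs are aggregated as mean +/- fold STD.
    """
    by_subject: dict[str, list] = {}
    for r in recordings:
        by_subject.setdefault(r.subject_id, []).append(r)
    rows = []
    for fold in range(folds.k):
        train_subj, test_subj = folds.train_test_subjects(fold)
        train = [r for s in train_subj for r in by_subject.get(s, [])]
        test = [r for s in test_subj for r in by_subject.get(s, [])]
        probs, truth = detector_run(train, test)
        probs, truth = np.asarray(probs, float), np.asarray(truth, int)
        if truth.min() == truth.max():
            raise ValueError(f"fold {fold} test set contains a single class")
        c = confusion(apply_threshold(probs, threshold), truth)
        row = metrics(c)
        row["balanced_accuracy"] = balanced_accuracy(c)
        if continuous and np.unique(probs).size > 2:
            roc, pr = roc_pr_curves(probs, truth)
            row["roc_auc"] = roc.auc
            row["pr_auc"] = pr.auc
        rows.append(row)
    return FoldReport(per_fold=pd.DataFrame(rows),
                      fold_assignment=dict(folds.assignment))
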