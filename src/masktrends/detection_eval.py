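"""Classifier-score evaluation: confusion metrics, ROC/AUC, threshold choice.

The pipeline treats per-image mask-classifier scores as given and turns
them into binary labels with an inclusive threshold (score >= t counts
positive). The operating threshold is chosen by the precision-maximizing
rule: among thresholds whose F1 is within a tolerance of the best F1, take
the one with the highest precision (largest threshold on ties). Undefined
ratios (zero denominators) are flagged, never coerced to 0.

Inter-rater reliability for hand-coded labels uses Krippendorff's alpha in
its nominal-metric coincidence-matrix form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "ThresholdRow",
    "RocCurve",
    "apply_threshold",
    "f1_score",
    "metrics_at",
    "threshold_table",
    "roc",
    "select_threshold",
    "krippendorff_alpha",
]


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall: 2PR/(P+R)."""
    if precision + recall == 0:
        raise ValueError("F1 undefined when precision + recall = 0")
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ThresholdRow:
    """Confusion counts and derived metrics at one decision threshold.

    ``precision``/``recall``/``f1`` are NaN with the matching ``*_defined``
    flag False when their denominator is zero.
    """

    threshold: float
    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True
    f1_defined: bool = True


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def apply_threshold(scores, threshold: float) -> np.ndarray:
    """Binary labels: 1 iff score >= threshold (boundary inclusive)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    scores = np.asarray(scores, dtype=float)
    return (scores >= threshold).astype(int)


def metrics_at(scores, truth, threshold: float) -> ThresholdRow:
    """Precision, recall, and F1 = 2PR/(P+R) at one threshold."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError(f"length mismatch: {scores.shape} scores vs {truth.shape} truth")
    pred = apply_threshold(scores, threshold)
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))

    p_def, r_def = (tp + fp) > 0, (tp + fn) > 0
    precision = tp / (tp + fp) if p_def else math.nan
    recall = tp / (tp + fn) if r_def else math.nan
    f1_def = p_def and r_def and (precision + recall) > 0
    f1 = 2 * precision * recall / (precision + recall) if f1_def else math.nan
    return ThresholdRow(
        threshold=threshold,
        counts=ConfusionCounts(tp, fp, fn, tn),
        precision=precision,
        recall=recall,
        f1=f1,
        precision_defined=p_def,
        recall_defined=r_def,
        f1_defined=f1_def,
    )


def threshold_table(scores, truth, thresholds) -> list[ThresholdRow]:
    return [metrics_at(scores, truth, t) for t in thresholds]


def rows_to_frame(rows: list[ThresholdRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": [r.threshold for r in rows],
            "tp": [r.counts.tp for r in rows],
            "fp": [r.counts.fp for r in rows],
            "fn": [r.counts.fn for r in rows],
            "tn": [r.counts.tn for r in rows],
            "precision": [r.precision for r in rows],
            "recall": [r.recall for r in rows],
            "f1": [r.f1 for r in rows],
        }
    )


def roc(scores, truth) -> RocCurve:
    """ROC curve over all distinct cutoffs with trapezoidal AUC.

    The trapezoidal area equals the rank statistic P(score+ > score-) with
    ties counted half. Raises if only one class is present.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    for cls in (0, 1):
        if not np.any(truth == cls):
            raise ValueError(f"ROC undefined: class {cls} absent from truth")
    fpr, tpr, thr = _sk_roc_curve(truth, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def select_threshold(rows: list[ThresholdRow], f1_tolerance: float = 0.01) -> float:
    """Precision-maximizing threshold among near-best-F1 candidates.

    Among rows with F1 >= max(F1) − f1_tolerance, return the threshold
    with maximal precision; precision ties go to the largest threshold.
    Row order does not matter.
    """
    usable = [r for r in rows if r.f1_defined]
    if not usable:
        raise ValueError("select_threshold needs at least one row with a defined F1")
    best_f1 = max(r.f1 for r in usable)
    candidates = [r for r in usable if r.f1 >= best_f1 - f1_tolerance]
    return max(candidates, key=lambda r: (r.precision, r.threshold)).threshold


def krippendorff_alpha(codings) -> float:
    """Krippendorff's alpha for nominal codings, missing entries allowed.

    ``codings`` is an items × coders array (NaN/None = missing). Builds the
    coincidence matrix from all ordered pairs of codings within an item,
    weighting each pair by 1/(m_u − 1), and returns
    1 − observed/expected disagreement. Raises if fewer than two items have
    two or more codings; returns 1.0 under zero expected disagreement with
    perfect agreement.
    """
    arr = pd.DataFrame(codings).to_numpy(dtype=float)
    values = np.unique(arr[~np.isnan(arr)])
    index = {v: i for i, v in enumerate(values)}
    k = len(values)
    coincidence = np.zeros((k, k))

    n_pairable_items = 0
    for row in arr:
        present = row[~np.isnan(row)]
        m = len(present)
        if m < 2:
            continue
        n_pairable_items += 1
        for a in present:
            for b in present:
                coincidence[index[a], index[b]] += 1.0 / (m - 1)
        coincidence[np.diag_indices(k)] -= np.array(
            [np.sum(present == v) for v in values]
        ) / (m - 1)
        # diagonal correction above removes self-pairs (a paired with itself)

    if n_pairable_items < 2:
        raise ValueError("Krippendorff's alpha undefined: fewer than 2 items with >= 2 codings")

    n_c = coincidence.sum(axis=1)
    n_total = n_c.sum()
    d_observed = coincidence.sum() - np.trace(coincidence)
    d_expected = n_total**2 - np.sum(n_c**2)  # up to a 1/(n-1) factor shared below
    if d_expected == 0:
        return 1.0 if d_observed == 0 else -math.inf
    return float(1.0 - (n_total - 1) * d_observed / d_expected)
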