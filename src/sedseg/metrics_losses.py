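"""Training loss and evaluation metrics for probability-map segmentation.

The training objective is the soft Dice loss

    loss(A, B) = 1 - (2 sum_i A_i B_i + eps) / (sum_i A_i^2 + sum_i B_i^2 + eps)

where ``A`` is the network's per-pixel probability map and ``B`` the
binary ground truth; the squared-denominator form keeps the loss
differentiable in ``A``.  The smoothing term ``eps`` (default 1.0) makes
the both-empty case evaluate to 1 (perfect agreement on "nothing there").

Evaluation uses count-based metrics on binarized masks:

    Accuracy = (TP + TN) / (TP + TN + FP + FN)
    IoU      = TP / (TP + FP + FN)
    DSC      = 2 TP / (2 TP + FP + FN)

with the convention IoU = DSC = 1 when TP + FP + FN = 0, plus ROC/AUC
over pooled pixel scores (trapezoidal area, which equals the
pairwise-concordance probability with ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "soft_dice",
    "dice_loss",
    "confusion",
    "accuracy",
    "iou",
    "dsc",
    "roc_curve",
    "roc_auc",
    "evaluate_cases",
    "write_report",
]


def _check_probability(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.size and (a.min() < 0.0 or a.max() > 1.0):
        raise ValueError("probability map values must lie in [0, 1]")
    return a


def _check_binary(b: np.ndarray, what: str = "mask") -> np.ndarray:
    b = np.asarray(b)
    if b.dtype != bool and not np.isin(b, (0, 1)).all():
        raise ValueError(f"{what} must be binary (0/1)")
    return b.astype(float)


def soft_dice(a: np.ndarray, b: np.ndarray, eps: float = 0.0) -> float:
    """Soft Dice overlap between a probability map and a binary mask.

    With ``eps=0`` (the default, reported values are exact formula
    evaluations) the both-empty case is defined as 1: predicting nothing
    where there is nothing is perfect agreement.  Training uses a
    smoothed variant (``eps=1``), which has the same limit.
    """
    a = _check_probability(a)
    b = _check_binary(b, "ground truth")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    num = 2.0 * float((a * b).sum()) + eps
    den = float((a * a).sum()) + float((b * b).sum()) + eps
    return 1.0 if den == 0.0 else num / den


def dice_loss(a: np.ndarray, b: np.ndarray, eps: float = 1.0) -> float:
    """``1 - soft_dice`` with smoothing; the quantity minimized during
    training (differentiable in ``a``; see ``sedseg.nn.dice_loss_and_grad``
    for the batched gradient form)."""
    return 1.0 - soft_dice(a, b, eps=eps)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts of a binary prediction vs. truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact TP/TN/FP/FN pixel counts."""
    p = _check_binary(pred, "prediction").astype(bool)
    t = _check_binary(truth, "truth").astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("accuracy is undefined on zero pixels")
    return (c.tp + c.tn) / c.total


def iou(c: ConfusionCounts) -> float:
    """Intersection over union; 1 by convention when nothing to find."""
    d = c.tp + c.fp + c.fn
    return 1.0 if d == 0 else c.tp / d


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity on counts; 1 by convention when nothing to find."""
    d = 2 * c.tp + c.fp + c.fn
    return 1.0 if d == 0 else 2 * c.tp / d


def roc_curve(scores: np.ndarray, truth: np.ndarray):
    """ROC points over descending unique score thresholds.

    Returns ``(fpr, tpr, thresholds)`` arrays; the curve starts at (0, 0)
    (threshold above every score) and ends at (1, 1).
    """
    s = np.asarray(scores, dtype=float).ravel()
    t = _check_binary(truth, "truth").ravel().astype(bool)
    if s.shape != t.shape:
        raise ValueError("scores and truth must have the same number of pixels")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative pixel")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    tps = np.cumsum(t[order])
    fps = np.cumsum(~t[order])
    # keep the last index of each tie group of scores
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[last]]
    return fpr, tpr, thresholds


def roc_auc(scores: np.ndarray, truth: np.ndarray):
    """ROC curve plus trapezoidal area under it.

    Returns ``((fpr, tpr, thresholds), auc)``.  The trapezoid over tie
    groups makes the area equal to the probability that a random positive
    pixel outscores a random negative one (ties counted 1/2).
    """
    fpr, tpr, thresholds = roc_curve(scores, truth)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thresholds), auc


def evaluate_cases(cases: Iterable[tuple]) -> pd.DataFrame:
    """Per-case accuracy / IoU / DSC table with an unweighted-mean summary.

    ``cases`` yields ``(case_id, predicted_mask, truth_mask)`` triples.
    The summary row (id ``"mean"``) is the plain average over cases, i.e.
    every test image counts equally regardless of its lesion size.
    """
    rows = []
    for case_id, pred, truth in cases:
        c = confusion(pred, truth)
        rows.append({"id": str(case_id), "acc": accuracy(c), "iou": iou(c), "dsc": dsc(c)})
    if not rows:
        raise ValueError("no cases to evaluate")
    df = pd.DataFrame(rows)
    summary = {"id": "mean", "acc": df["acc"].mean(), "iou": df["iou"].mean(),
               "dsc": df["dsc"].mean()}
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


def write_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_roc_points(fpr: np.ndarray, tpr: np.ndarray, path) -> None:
    """Export ROC curve points as a two-column (fpr, tpr) CSV table."""
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(path, index=False)
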