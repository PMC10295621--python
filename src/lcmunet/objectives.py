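"""Training loss and evaluation metrics for binary segmentation.

The training objective is a compound of soft Dice and binary cross-entropy:

    loss = dice(y', y) + 0.5 * bce(y', y)

with soft Dice ``1 - (2*sum(p*y) + eps) / (sum(p) + sum(y) + eps)``
(eps = 1 for stability on empty masks) and BCE averaged over pixels on
probabilities clipped to [1e-7, 1 - 1e-7].

Evaluation uses pixel confusion counts at threshold 0.5 and the standard
ratios

    IoU       = TP / (TP + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 TP / (2 TP + FP + FN)

Counts are pooled globally over the evaluated set by default (per-image
averaging is available in the pipeline).  Degenerate 0/0 ratios resolve to
1.0 when both prediction and ground truth are empty, else 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .tensor import Tensor

DICE_EPS = 1.0
BCE_CLIP = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricSet:
    iou: float
    recall: float
    precision: float
    f1: float

    def as_percent(self) -> dict[str, float]:
        return {k: round(100.0 * v, 2) for k, v in
                (("iou", self.iou), ("recall", self.recall),
                 ("precision", self.precision), ("f1", self.f1))}


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def dice_bce_loss(pred, target):
    """Compound Dice + 0.5*BCE loss; differentiable when ``pred`` is a Tensor."""
    t = _as_array(target).astype(np.float32)
    if isinstance(pred, Tensor):
        if pred.shape != t.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {t.shape}")
        tt = Tensor(t)
        inter = T.tsum(pred * tt)
        dice = 1.0 - (2.0 * inter + DICE_EPS) * _reciprocal(
            T.tsum(pred) + T.tsum(tt) + DICE_EPS)
        p = T.clip(pred, BCE_CLIP, 1.0 - BCE_CLIP)
        bce = -T.tmean(tt * T.log(p) + (1.0 - tt) * T.log(1.0 - p))
        return dice + 0.5 * bce
    p = np.asarray(pred, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    inter = float((p * t).sum())
    dice = 1.0 - (2.0 * inter + DICE_EPS) / (p.sum() + t.sum() + DICE_EPS)
    pc = np.clip(p, BCE_CLIP, 1.0 - BCE_CLIP)
    bce = float(-(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).mean())
    return dice + 0.5 * bce


def _reciprocal(x: Tensor) -> Tensor:
    out = Tensor(1.0 / x.data, parents=(x,))
    out._backward = lambda g: x._accumulate(-g / (x.data * x.data))
    return out


def confusion_counts(pred, target, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold the probability map and tally pixel outcomes."""
    p = _as_array(pred)
    t = _as_array(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    ph = p >= threshold
    th = t >= 0.5
    tp = int(np.count_nonzero(ph & th))
    fp = int(np.count_nonzero(ph & ~th))
    fn = int(np.count_nonzero(~ph & th))
    tn = int(np.count_nonzero(~ph & ~th))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, empty_case: bool) -> float:
    if den == 0:
        return 1.0 if empty_case else 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """Exact metric ratios from confusion counts, with 0/0 sentinels."""
    empty = c.tp == 0 and c.fp == 0 and c.fn == 0
    return MetricSet(
        iou=_ratio(c.tp, c.tp + c.fp + c.fn, empty),
        recall=_ratio(c.tp, c.tp + c.fn, empty),
        precision=_ratio(c.tp, c.tp + c.fp, empty),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, empty),
    )


def evaluate_predictions(preds, targets, *, threshold: float = 0.5,
                         per_image: bool = False):
    """Metrics over a set of predictions.

    Global mode pools confusion counts over all pixels before computing the
    ratios; per-image mode computes a MetricSet per sample and returns the
    arithmetic mean alongside the individual rows.
    """
    pairs = list(zip(preds, targets))
    if not pairs:
        raise ValueError("cannot evaluate an empty sample set")
    if per_image:
        rows = [metrics(confusion_counts(p, t, threshold)) for p, t in pairs]
        mean = MetricSet(*(float(np.mean([getattr(r, k) for r in rows]))
                           for k in ("iou", "recall", "precision", "f1")))
        return mean, rows
    total = ConfusionCounts(0, 0, 0, 0)
    for p, t in pairs:
        total = total + confusion_counts(p, t, threshold)
    return metrics(total)
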