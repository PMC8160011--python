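"""Dice coefficient, dice losses and confusion-matrix metrics.

The dice coefficient between pixel sets X and Y is
``2|X ∩ Y| / (|X| + |Y|)``; its soft relaxation over a probability map
p and binary target t,

    1 - (2 Σ p·t + eps) / (Σ p + Σ t + eps),

is the training loss.  For hybrid two-channel targets the loss is the
unweighted mean of the per-channel soft dice losses.  Pixel-level
confusion counts give accuracy (TP+TN)/(TP+FP+TN+FN), sensitivity
TP/(TP+FN) and specificity TN/(FP+TN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labeling import BinaryMask, LabelBundle, LabelMode, Polarity

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "dice_coefficient",
    "soft_dice_loss",
    "hybrid_dice_loss",
    "confusion_metrics",
]

DEFAULT_EPS = 1e-6


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsReport:
    """Dice plus confusion-derived metrics for one evaluation scope.

    ``sensitivity`` is None when the ground truth has no positives and
    ``specificity`` is None when it has no negatives (undefined, not an
    error).
    """

    dice: float
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    counts: ConfusionCounts
    scope: str = "per-slice"
    case_id: str = ""

    def to_row(self) -> dict:
        """Flat dict for CSV/JSON serialization."""
        return {
            "case_id": self.case_id,
            "scope": self.scope,
            "dice": self.dice,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "TP": self.counts.tp,
            "TN": self.counts.tn,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
        }


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice_coefficient(x: BinaryMask, y: BinaryMask) -> float:
    """2|X∩Y| / (|X|+|Y|); defined as 1.0 when both masks are empty.

    An empty-vs-empty slice is a correct outcome (no nodule, none
    predicted), hence the 1.0 convention.
    """
    _check_shapes(x.pixels, y.pixels)
    inter = int(np.logical_and(x.pixels, y.pixels).sum())
    size = int(x.pixels.sum()) + int(y.pixels.sum())
    if size == 0:
        return 1.0
    return 2.0 * inter / size


def soft_dice_loss(pred: np.ndarray, target: BinaryMask | np.ndarray,
                   eps: float = DEFAULT_EPS) -> float:
    """1 - (2 Σ p·t + eps) / (Σp + Σt + eps), differentiable in p."""
    pred = np.asarray(pred, dtype=np.float64)
    t = target.pixels.astype(np.float64) if isinstance(target, BinaryMask) \
        else np.asarray(target, dtype=np.float64)
    _check_shapes(pred, t)
    num = 2.0 * float(np.sum(pred * t)) + eps
    den = float(np.sum(pred)) + float(np.sum(t)) + eps
    return 1.0 - num / den


def hybrid_dice_loss(pred: np.ndarray, bundle: LabelBundle,
                     eps: float = DEFAULT_EPS) -> float:
    """Mean of the per-channel soft dice losses of a hybrid bundle.

    Channel 0 is scored against the positive label, channel 1 against
    the complementary label.
    """
    if bundle.mode is not LabelMode.HYBRID:
        raise ValueError(f"expected a hybrid bundle, got {bundle.mode.value}")
    pred = np.asarray(pred, dtype=np.float64)
    if pred.ndim != 3 or pred.shape[0] != 2:
        raise ValueError(f"expected a (2, H, W) prediction, got {pred.shape}")
    losses = [soft_dice_loss(pred[k], bundle.channels[k], eps) for k in range(2)]
    return float(np.mean(losses))


def confusion_metrics(pred: BinaryMask, gt: BinaryMask,
                      scope: str = "per-slice", case_id: str = "") -> MetricsReport:
    """Pixel-level confusion counts and the derived metric triplet."""
    _check_shapes(pred.pixels, gt.pixels)
    if pred.polarity is not gt.polarity:
        raise ValueError(
            f"polarity mismatch: pred {pred.polarity.value} vs gt {gt.polarity.value}"
        )
    p, g = pred.pixels, gt.pixels
    tp = int(np.sum(p & g))
    tn = int(np.sum(~p & ~g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    counts = ConfusionCounts(tp, tn, fp, fn)
    accuracy = (tp + tn) / counts.total
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (fp + tn) if (fp + tn) > 0 else None
    dice = dice_coefficient(pred, gt)
    return MetricsReport(dice=dice, accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, counts=counts,
                         scope=scope, case_id=case_id)


def report_from_counts(counts: ConfusionCounts, scope: str = "pooled",
                       case_id: str = "") -> MetricsReport:
    """Metrics recomputed from pooled confusion counts.

    Pooled dice uses the binary identity dice = 2TP / (2TP + FP + FN).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    accuracy = (tp + tn) / counts.total if counts.total else 1.0
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (fp + tn) if (fp + tn) > 0 else None
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 1.0
    return MetricsReport(dice=dice, accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, counts=counts,
                         scope=scope, case_id=case_id)
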