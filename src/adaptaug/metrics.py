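"""Segmentation metrics: confusion counts, the five pixel indexes, per-image
IoU, the test-set Dice ratio and the step reward.

For binary masks with 1 = disease spot, the confusion counts are

    K_TP = |pred & truth|      K_FP = |pred & ~truth|
    K_FN = |~pred & truth|     K_TN = |~pred & ~truth|

and the five indexes are

    PA   = (K_TP + K_TN) / total
    MPA  = ((K_TP/(K_TP+K_FP)) + (K_TN/(K_TN+K_FN))) / 2
    CPA  = K_TP / (K_TP + K_FP)
    IoU  = K_TP / (K_TP + K_FN + K_FP)
    MIoU = ((K_TP/(K_TP+K_FN+K_FP)) + (K_TN/(K_TN+K_FP+K_FN))) / 2

Any 0/0 term is defined as 1 — an absent class predicted absent is a perfect
prediction; this keeps metrics defined on spot-free images.

The Dice ratio over a test set is d = (dice_factor / n) * sum(per-image IoU)
with dice_factor = 2 by default, so d ranges over [0, 2]; the reward of a
step is r = 100 * (d_t - d_{t-1}), which only sees differences, so the
factor rescales rewards uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "DiceScore",
    "confusion_counts",
    "compute_metrics",
    "image_iou",
    "dice_ratio",
    "reward",
    "DICE_FACTOR",
]

DICE_FACTOR = 2.0


@dataclass(frozen=True)
class ConfusionCounts:
    K_TP: int
    K_FP: int
    K_TN: int
    K_FN: int

    def __post_init__(self) -> None:
        if min(self.K_TP, self.K_FP, self.K_TN, self.K_FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.K_TP + self.K_FP + self.K_TN + self.K_FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.K_TP + other.K_TP, self.K_FP + other.K_FP,
                               self.K_TN + other.K_TN, self.K_FN + other.K_FN)


@dataclass(frozen=True)
class MetricSet:
    PA: float
    MPA: float
    CPA: float
    IoU: float
    MIoU: float

    def as_dict(self) -> dict[str, float]:
        return {"PA": self.PA, "MPA": self.MPA, "CPA": self.CPA,
                "IoU": self.IoU, "MIoU": self.MIoU}


@dataclass(frozen=True)
class DiceScore:
    """d = (dice_factor / n_test) * sum of per-image IoU; in [0, dice_factor]."""

    d: float
    n_test: int


def _check_binary_pair(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary over {{0,1}}, got values {vals}")


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-level confusion counts of a predicted vs expected binary mask."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_binary_pair(pred, truth)
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        K_TP=int(np.count_nonzero(p & t)),
        K_FP=int(np.count_nonzero(p & ~t)),
        K_TN=int(np.count_nonzero(~p & ~t)),
        K_FN=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: float, den: float) -> float:
    """num/den with the 0/0 -> 1 convention (absent class predicted absent)."""
    if den == 0:
        return 1.0 if num == 0 else 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The five pixel indexes from one set of confusion counts."""
    if c.total <= 0:
        raise ValueError("total pixel count must be positive")
    tp, fp, tn, fn = c.K_TP, c.K_FP, c.K_TN, c.K_FN
    return MetricSet(
        PA=(tp + tn) / c.total,
        MPA=0.5 * (_ratio(tp, tp + fp) + _ratio(tn, tn + fn)),
        CPA=_ratio(tp, tp + fp),
        IoU=_ratio(tp, tp + fn + fp),
        MIoU=0.5 * (_ratio(tp, tp + fn + fp) + _ratio(tn, tn + fp + fn)),
    )


def image_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks; 1 if both are empty."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_binary_pair(pred, truth)
    p = pred.astype(bool)
    t = truth.astype(bool)
    union = int(np.count_nonzero(p | t))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(p & t)) / union


def dice_ratio(per_image_ious: Sequence[float],
               dice_factor: float = DICE_FACTOR) -> DiceScore:
    """Test-set Dice ratio: dice_factor times the mean per-image IoU."""
    ious = np.asarray(list(per_image_ious), dtype=float)
    if ious.size == 0:
        raise ValueError("need at least one per-image IoU")
    if ious.min() < 0 or ious.max() > 1:
        raise ValueError("per-image IoU values must lie in [0, 1]")
    return DiceScore(d=float(dice_factor * ious.mean()), n_test=int(ious.size))


def reward(d_t: float, d_prev: float) -> float:
    """Step reward: 100 times the change in the Dice ratio."""
    if not (np.isfinite(d_t) and np.isfinite(d_prev)):
        raise ValueError("Dice values must be finite")
    return 100.0 * (d_t - d_prev)
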