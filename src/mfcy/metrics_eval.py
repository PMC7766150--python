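"""Segmentation metrics, cross-validation folds, and fold summaries.

Metrics are the four pixel-wise scores IoU (Jaccard), Dice, precision and
recall, all derived from a single confusion count:

    IoU = TP/(TP+FP+FN)      Dice = 2TP/(2TP+FP+FN)
    Precision = TP/(TP+FP)   Recall = TP/(TP+FN)

When both prediction and ground truth are empty every denominator is 0;
by convention those metrics are scored 1 with an ``empty-agreement`` flag
(agreement on absence) so batch means stay defined, and flagged rows can
be reported separately.  A 0/0 with a non-empty counterpart is undefined
(NaN) and flagged.

Cross-validation uses five folds that never split a group (case by
default, so the same fetus cannot appear in both train and test), with
fold sizes as balanced as the grouping permits.  Fold summaries are the
arithmetic mean and the population (divide-by-n) standard deviation of
the five per-fold means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np

from .mask_core import as_binary_mask

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "FoldAssignment",
    "confusion",
    "metrics_from_counts",
    "iou_score",
    "delta_iou",
    "five_fold_split",
    "summarize_folds",
]

Grouping = Literal["case", "video", "image"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricRecord:
    """Per-image metric values; NaN marks an undefined ratio."""

    image_id: str
    iou: float
    dice: float
    precision: float
    recall: float
    flags: Tuple[str, ...] = ()


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies of TP/FP/FN/TN between two binary masks."""
    p = as_binary_mask(pred).astype(bool)
    g = as_binary_mask(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, both_empty: bool) -> tuple[float, str | None]:
    if den > 0:
        return num / den, None
    if both_empty:
        return 1.0, "empty-agreement"
    return math.nan, "undefined"


def metrics_from_counts(c: ConfusionCounts, image_id: str = "") -> MetricRecord:
    """IoU, Dice, precision and recall from one confusion count."""
    both_empty = c.tp == 0 and c.fp == 0 and c.fn == 0
    iou, f1 = _ratio(c.tp, c.tp + c.fp + c.fn, both_empty)
    dice, f2 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, both_empty)
    precision, f3 = _ratio(c.tp, c.tp + c.fp, both_empty)
    recall, f4 = _ratio(c.tp, c.tp + c.fn, both_empty)
    flags = tuple(sorted({f for f in (f1, f2, f3, f4) if f}))
    return MetricRecord(
        image_id=image_id,
        iou=iou,
        dice=dice,
        precision=precision,
        recall=recall,
        flags=flags,
    )


def iou_score(pred: np.ndarray, gt: np.ndarray) -> float:
    """Convenience: IoU of one mask pair (empty vs empty scores 1)."""
    return metrics_from_counts(confusion(pred, gt)).iou


def delta_iou(
    pred_method: np.ndarray, pred_baseline: np.ndarray, gt: np.ndarray
) -> float:
    """Per-image IoU improvement of a method over a baseline, in [-1, 1].

    An undefined baseline IoU (empty prediction against non-empty ground
    truth has IoU 0, so this only arises through NaN propagation) yields NaN.
    """
    return iou_score(pred_method, gt) - iou_score(pred_baseline, gt)


@dataclass
class FoldAssignment:
    """Mapping image_id -> fold number in 0..4, grouped so related images
    (same case or video) never straddle folds."""

    fold_of: Dict[str, int]
    grouping: Grouping

    def fold_sizes(self) -> List[int]:
        sizes = [0] * 5
        for f in self.fold_of.values():
            sizes[f] += 1
        return sizes

    def members(self, fold: int) -> List[str]:
        return sorted(k for k, v in self.fold_of.items() if v == fold)


def five_fold_split(
    items: Sequence[Tuple[str, str, str]],
    grouping: Grouping = "case",
    seed: int = 0,
) -> FoldAssignment:
    """Partition images into five folds without splitting any group.

    ``items`` are (image_id, case_id, video_id) rows.  Groups are shuffled
    deterministically from ``seed``, then assigned largest-first to the
    currently smallest fold, which balances fold sizes up to the largest
    group size.  Requires at least five groups.
    """
    if not items:
        raise ValueError("need at least one item")
    ids = [row[0] for row in items]
    if len(set(ids)) != len(ids):
        raise ValueError("image_id values must be unique")

    key_index = {"image": 0, "case": 1, "video": 2}[grouping]
    groups: Dict[str, List[str]] = {}
    for row in items:
        groups.setdefault(row[key_index], []).append(row[0])
    if len(groups) < 5:
        raise ValueError(
            f"five-fold split needs >= 5 {grouping} groups, got {len(groups)}; "
            "use a finer grouping or more data"
        )

    rng = np.random.default_rng(seed)
    names = sorted(groups)
    order = [names[i] for i in rng.permutation(len(names))]
    # Largest group first; shuffle breaks ties among equal-sized groups.
    order.sort(key=lambda g: -len(groups[g]))

    sizes = [0] * 5
    fold_of: Dict[str, int] = {}
    for g in order:
        fold = min(range(5), key=lambda f: (sizes[f], f))
        for image_id in groups[g]:
            fold_of[image_id] = fold
        sizes[fold] += len(groups[g])
    return FoldAssignment(fold_of=fold_of, grouping=grouping)


def summarize_folds(per_fold_means: Sequence[float]) -> Tuple[float, float]:
    """Mean and population (divide-by-n) SD of exactly five per-fold means."""
    if len(per_fold_means) != 5:
        raise ValueError(f"expected exactly 5 per-fold means, got {len(per_fold_means)}")
    arr = np.asarray(per_fold_means, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))
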