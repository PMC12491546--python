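"""Segmentation evaluation: overlap metrics, surface distances, ROC/AUC,
qualitative overlays and fold aggregation.

All fraction metrics are defined on pixel-wise confusion counts between a
predicted mask A and ground truth B.  Conventions for degenerate inputs: the
empty-vs-empty Dice is 1.0; any other metric whose denominator is empty
yields NaN (logged), and NaN entries are excluded from aggregation.
Distances are Euclidean, in pixels, between 4-connectivity boundaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "confusion",
    "dsc",
    "iou",
    "se",
    "sp",
    "acc",
    "surface_distances",
    "roc_auc",
    "evaluate_masks",
    "aggregate",
    "overlay",
    "report_to_json",
    "report_to_csv",
]

FRACTION_METRICS = ("dsc", "iou", "se", "sp", "acc")
ALL_METRICS = FRACTION_METRICS + ("hd", "assd", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _validate_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    a = _validate_binary(pred, "pred")
    b = _validate_binary(truth, "truth")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return ConfusionCounts(
        tp=int((a & b).sum()),
        fp=int((a & ~b).sum()),
        fn=int((~a & b).sum()),
        tn=int((~a & ~b).sum()),
    )


def dsc(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0  # both masks empty: perfect agreement by convention
    return 2 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    return _guarded(c.tp, c.tp + c.fp + c.fn, "iou")


def _guarded(num: int, denom: int, name: str) -> float:
    if denom == 0:
        logger.warning("%s undefined (empty denominator); reporting NaN", name)
        return float("nan")
    return num / denom


def se(c: ConfusionCounts) -> float:
    """Sensitivity TP/(TP+FN)."""
    return _guarded(c.tp, c.tp + c.fn, "sensitivity")


def sp(c: ConfusionCounts) -> float:
    """Specificity TN/(TN+FP)."""
    return _guarded(c.tn, c.tn + c.fp, "specificity")


def acc(c: ConfusionCounts) -> float:
    return _guarded(c.tp + c.tn, c.total, "accuracy")


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one background 4-neighbor (image border
    counts as background)."""
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return mask & ~interior


def surface_distances(pred, truth):
    """(Hausdorff, average symmetric surface distance) in pixels.

    HD is the larger directed maximum boundary distance; ASSD the mean of
    the two directed average distances.  NaN if either mask is empty.
    """
    a = _validate_binary(pred, "pred")
    b = _validate_binary(truth, "truth")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        logger.warning("surface distance undefined for an empty mask")
        return float("nan"), float("nan")
    pa = np.argwhere(_boundary(a))
    pb = np.argwhere(_boundary(b))
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    hd = max(d_ab.max(), d_ba.max())
    assd = 0.5 * (d_ab.mean() + d_ba.mean())
    return float(hd), float(assd)


def roc_auc(probabilities: Sequence[np.ndarray],
            truths: Sequence[np.ndarray]) -> float:
    """Pixel-pooled AUC over the whole evaluation set (one global ROC)."""
    scores = np.concatenate([np.asarray(p).ravel() for p in probabilities])
    labels = np.concatenate(
        [_validate_binary(t, "truth").ravel() for t in truths]
    )
    if labels.all() or not labels.any():
        logger.warning("AUC undefined for single-class ground truth")
        return float("nan")
    return float(roc_auc_score(labels, scores))


def evaluate_masks(pred, truth) -> Dict[str, float]:
    """Per-image report of all overlap and distance metrics."""
    c = confusion(pred, truth)
    hd, assd = surface_distances(pred, truth)
    return {
        "dsc": dsc(c),
        "iou": iou(c),
        "se": se(c),
        "sp": sp(c),
        "acc": acc(c),
        "hd": hd,
        "assd": assd,
    }


def aggregate(per_image: List[Dict[str, float]], folds: int = 1
              ) -> Dict[str, Dict[str, float]]:
    """mean +- population std per metric; NaN sentinels excluded.

    With ``folds`` > 1 the list is chunked into folds, averaged per fold,
    then mean/std taken across fold means.
    """
    if not per_image:
        raise ValueError("empty report list")
    keys = sorted({k for rep in per_image for k in rep})
    out: Dict[str, Dict[str, float]] = {}
    chunks = np.array_split(np.arange(len(per_image)), folds)
    for key in keys:
        fold_means = []
        n_excluded = 0
        for chunk in chunks:
            vals = np.array([per_image[i].get(key, np.nan) for i in chunk])
            good = vals[~np.isnan(vals)]
            n_excluded += int(np.isnan(vals).sum())
            if folds == 1:
                fold_means = list(good)  # single fold: spread over images
            elif good.size:
                fold_means.append(good.mean())
        if n_excluded:
            logger.warning(
                "%s: excluded %d undefined entries from aggregation",
                key, n_excluded,
            )
        fm = np.array(fold_means)
        out[key] = {
            "mean": float(fm.mean()) if fm.size else float("nan"),
            "std": float(fm.std()) if fm.size else float("nan"),
            "n_excluded": n_excluded,
        }
    return out


def overlay(pred, truth, image: Optional[np.ndarray] = None,
            alpha: float = 0.5) -> np.ndarray:
    """Qualitative error map: yellow = TP, red = FN (missed), green = FP.

    ``image`` is (H, W, 3) uint8 or float in [0, 1]; omitted -> black canvas.
    Returns uint8 (H, W, 3).
    """
    a = _validate_binary(pred, "pred")
    b = _validate_binary(truth, "truth")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if image is None:
        canvas = np.zeros(a.shape + (3,), dtype=np.float64)
    else:
        canvas = np.asarray(image, dtype=np.float64)
        if canvas.max() > 1.0:
            canvas = canvas / 255.0
    colors = {
        "tp": (a & b, (1.0, 1.0, 0.0)),
        "fn": (~a & b, (1.0, 0.0, 0.0)),
        "fp": (a & ~b, (0.0, 1.0, 0.0)),
    }
    for region, color in colors.values():
        canvas[region] = (1 - alpha) * canvas[region] + alpha * np.array(color)
    return (np.clip(canvas, 0, 1) * 255).round().astype(np.uint8)


def report_to_json(path, per_image, aggregated) -> None:
    with open(path, "w") as fh:
        json.dump({"per_image": per_image, "aggregate": aggregated}, fh,
                  indent=2, allow_nan=True)


def report_to_csv(path, per_image: List[Dict[str, float]]) -> None:
    keys = sorted({k for rep in per_image for k in rep})
    with open(path, "w") as fh:
        fh.write("index," + ",".join(keys) + "\n")
        for i, rep in enumerate(per_image):
            fh.write(
                f"{i}," + ",".join(f"{rep.get(k, float('nan'))}" for k in keys)
                + "\n"
            )
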