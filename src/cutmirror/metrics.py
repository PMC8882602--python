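"""Segmentation evaluation: Dice overlap, Hausdorff boundary distance,
and paired method comparison by the Wilcoxon signed-rank test.

The Hausdorff distance is computed between *boundary* point sets rather
than full masks — it is meant to be sensitive to boundary placement.
All distances are in pixels; no physical spacing is assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import wilcoxon

from .augmentation import as_binary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(gt: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts between two same-shape binary masks."""
    gt = as_binary(gt)
    pred = as_binary(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    tp = int(np.count_nonzero(gt & pred))
    fp = int(np.count_nonzero(~gt & pred))
    fn = int(np.count_nonzero(gt & ~pred))
    tn = int(np.count_nonzero(~gt & ~pred))
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient, 2*TP / (2*TP + FP + FN).

    When both masks are empty the coefficient is undefined by the
    formula; it is reported as 1.0 (a correctly predicted absent lesion
    is not penalized) with a logged warning.
    """
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        logger.warning("DSC of two empty masks; reporting 1.0 by convention")
        return 1.0
    return 2.0 * c.tp / denom


def dice(gt: np.ndarray, pred: np.ndarray) -> float:
    """Convenience wrapper: Dice coefficient of two masks."""
    return dsc(confusion(gt, pred))


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one 4-neighbor outside the mask,
    as an (n, 2) array of (row, col)."""
    mask = as_binary(mask)
    if not mask.any():
        return np.empty((0, 2), dtype=float)
    interior = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1))
    edge = mask & ~interior
    return np.argwhere(edge).astype(float)


def hausdorff(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two non-empty point sets
    under the Euclidean metric: the larger of the two directed maximal
    nearest-point distances."""
    x = np.asarray(x, dtype=float).reshape(-1, 2)
    y = np.asarray(y, dtype=float).reshape(-1, 2)
    if x.size == 0 or y.size == 0:
        raise ValueError("undefined Hausdorff: empty point set")
    dxy = directed_hausdorff(x, y)[0]
    dyx = directed_hausdorff(y, x)[0]
    return float(max(dxy, dyx))


def hausdorff_masks(gt: np.ndarray, pred: np.ndarray) -> float:
    """Hausdorff distance between the boundary point sets of two masks."""
    return hausdorff(boundary_points(gt), boundary_points(pred))


def compare_methods(scores_a: list[float] | np.ndarray, scores_b: list[float] | np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-case scores.

    Pairs with zero difference are discarded (the classical Wilcoxon
    procedure); if every difference is zero the methods are
    indistinguishable and p = 1.0 is returned with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    if a.size < 6:
        raise ValueError("need at least 6 paired cases for the signed-rank test")
    if np.all(a == b):
        logger.warning("all paired differences are zero; p-value reported as 1.0")
        return 1.0
    return float(wilcoxon(a, b, alternative="two-sided").pvalue)
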