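"""Segmentation evaluation: Dice overlap, pooled average Dice, accuracy.

Clustering output is permutation-invariant, so before any metric the
predicted cluster indices are matched one-to-one to the ground-truth
classes.  The default matching maximizes total overlap on the contingency
table (optimal assignment); an intensity-ordering alternative is available
for T1 images where background < CSF < GM < WM.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import MetricsReport

TISSUE_NAMES = {0: "background", 1: "CSF", 2: "GM", 3: "WM"}


def _as_labels(a: np.ndarray) -> np.ndarray:
    return np.asarray(a).ravel().astype(np.int64)


def contingency(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> np.ndarray:
    """n×n table of pixel counts, rows = predicted cluster, cols = truth class."""
    pred, truth = _as_labels(pred), _as_labels(truth)
    if pred.shape != truth.shape:
        raise ValueError("label maps must have the same size")
    for name, lab in (("pred", pred), ("truth", truth)):
        if lab.min() < 0 or lab.max() >= n_classes:
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    return np.bincount(
        pred * n_classes + truth, minlength=n_classes * n_classes
    ).reshape(n_classes, n_classes)


def align_clusters(
    pred: np.ndarray, truth: np.ndarray, n_classes: int
) -> dict[int, int]:
    """One-to-one map predicted-cluster -> truth-class maximizing total overlap.

    Solved as an optimal assignment on the contingency table; among
    equally good assignments the one reached first in row-major class
    order is returned (deterministic).
    """
    table = contingency(pred, truth, n_classes)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def align_by_intensity(centroids: np.ndarray) -> dict[int, int]:
    """Map clusters to classes by centroid order (T1: bg < CSF < GM < WM)."""
    order = np.argsort(np.asarray(centroids))
    return {int(cluster): rank for rank, cluster in enumerate(order)}


def relabel(pred: np.ndarray, alignment: dict[int, int]) -> np.ndarray:
    """Rewrite predicted cluster indices as their aligned truth classes."""
    pred = np.asarray(pred)
    lut = np.arange(max(alignment) + 1)
    for cluster, cls in alignment.items():
        lut[cluster] = cls
    return lut[pred]


def dice(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if pred_mask.shape != truth_mask.shape:
        raise ValueError("masks must have the same shape")
    total = int(pred_mask.sum()) + int(truth_mask.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((pred_mask & truth_mask).sum()) / total


def dice_average(
    pred: np.ndarray,
    truth: np.ndarray,
    alignment: dict[int, int],
    tissue_classes: tuple[int, ...] = (1, 2, 3),
) -> float:
    """Pooled average Dice over the brain tissues, background excluded.

    Overlaps and mask sizes are pooled over CSF, GM and WM before the
    ratio is taken — this is NOT the arithmetic mean of per-tissue Dice:

        DSC_av = 2 * sum_c |A_c ∩ B_c| / sum_c (|A_c| + |B_c|)
    """
    aligned = _as_labels(relabel(pred, alignment))
    truth = _as_labels(truth)
    inter = 0
    sizes = 0
    for c in tissue_classes:
        a, b = aligned == c, truth == c
        inter += int((a & b).sum())
        sizes += int(a.sum()) + int(b.sum())
    return 1.0 if sizes == 0 else 2.0 * inter / sizes


def segmentation_accuracy(
    pred: np.ndarray, truth: np.ndarray, alignment: dict[int, int]
) -> float:
    """Fraction of pixels whose aligned label matches truth (all classes)."""
    aligned = _as_labels(relabel(pred, alignment))
    truth = _as_labels(truth)
    if aligned.shape != truth.shape:
        raise ValueError("label maps must have the same size")
    return float(np.mean(aligned == truth))


def evaluate_segmentation(
    pred: np.ndarray,
    truth: np.ndarray,
    n_classes: int = 4,
    alignment: dict[int, int] | None = None,
) -> MetricsReport:
    """Full report: per-tissue Dice, pooled average Dice, accuracy."""
    if alignment is None:
        alignment = align_clusters(pred, truth, n_classes)
    aligned = relabel(pred, alignment)
    per_class = {}
    for c in range(n_classes):
        name = TISSUE_NAMES.get(c, f"class{c}")
        per_class[name] = dice(np.asarray(aligned) == c, np.asarray(truth) == c)
    return MetricsReport(
        dsc_per_class=per_class,
        dsc_av=dice_average(pred, truth, alignment),
        sa=segmentation_accuracy(pred, truth, alignment),
        alignment=alignment,
    )
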