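"""The trivial internal-air lung "segmenter" and baseline-aware evaluation.

A lung CT can be "segmented" embarrassingly well by marking every voxel
darker than −400 HU as air and discarding the air outside the body: the
result contains the lungs but also the trachea and any bowel gas, so it is
anatomically wrong — yet its Dice against the true lung mask is high,
because the lungs dominate the internal air volume.  Any serious lung
segmentation model must beat this baseline before its Dice means anything.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .metrics import dice, iou, summarize_scores
from .volumes import BinaryMask3D, CTVolume

__all__ = [
    "AIR_THRESHOLD_HU",
    "threshold_air",
    "remove_border_air",
    "baseline_lung_proxy",
    "evaluate_baseline",
]

AIR_THRESHOLD_HU = -400.0


def threshold_air(volume: CTVolume, threshold: float = AIR_THRESHOLD_HU) -> BinaryMask3D:
    """Mark voxels strictly below the threshold (default −400 HU) as air."""
    return BinaryMask3D(volume.hu < threshold, spacing=volume.spacing)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def remove_border_air(air: BinaryMask3D, connectivity: int = 6) -> BinaryMask3D:
    """Drop air components connected to any face of the grid (exterior air)."""
    labels, n = ndimage.label(air.values, structure=_structure(connectivity))
    if n == 0:
        return BinaryMask3D(np.zeros_like(air.values), spacing=air.spacing)
    border = np.zeros_like(air.values, dtype=bool)
    for ax in range(3):
        sl: list = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
        sl[ax] = slice(None)
    border_labels = np.unique(labels[border & air.values])
    keep = ~np.isin(labels, border_labels) & air.values
    return BinaryMask3D(keep, spacing=air.spacing)


def baseline_lung_proxy(volume: CTVolume, connectivity: int = 6) -> BinaryMask3D:
    """Internal-air mask: threshold at −400 HU, then strip exterior air."""
    return remove_border_air(threshold_air(volume), connectivity=connectivity)


def evaluate_baseline(
    volumes_with_truths: list[tuple[CTVolume, BinaryMask3D]],
) -> dict:
    """Score the internal-air proxy against lung truths over a cohort.

    Returns per-volume Dice/IoU rows plus min/mean/max/SD summaries for each
    metric, the Table-style report that exposes how high the overlap scores
    of an anatomically wrong baseline can be.
    """
    if not volumes_with_truths:
        raise ValueError("need at least one (volume, truth) pair")
    rows = []
    for i, (volume, truth) in enumerate(volumes_with_truths):
        if volume.shape != truth.shape:
            raise ValueError(f"volume {i}: truth shape {truth.shape} != {volume.shape}")
        pred = baseline_lung_proxy(volume)
        extra = int((pred.values & ~truth.values).sum())
        rows.append(
            {
                "volume": i,
                "dice": dice(pred.values, truth.values),
                "iou": iou(pred.values, truth.values),
                "predicted_voxels": pred.count(),
                "truth_voxels": truth.count(),
                "non_lung_predicted_voxels": extra,
            }
        )
    return {
        "per_volume": rows,
        "summary": {
            "dice": summarize_scores([r["dice"] for r in rows]),
            "iou": summarize_scores([r["iou"] for r in rows]),
        },
    }
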