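"""Class activation maps: computation, scaling, binarization, localization.

A class activation map merges the final-layer feature maps with the head
weights of one class, ``M_c(i,j) = sum_k w_{k,c} f_k(i,j)``. Because the
head is bias-free, the spatial sum of ``M_c`` equals the class score
``S_c`` exactly — the map is a faithful decomposition of the decision.
Maps are min–max scaled to [0,1], bilinearly upsampled to the resolution of
the ground-truth annotation, and thresholded at 0.3 (inclusive). A lesion
counts as localized when the binary map overlaps the annotation by at least
one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from skimage.transform import resize as _sk_resize

from .models import ClassifierForward
from .stats import ContingencyTable2x2

DEFAULT_CAM_THRESHOLD = 0.3

ClassPolicy = Literal["predicted", "true_class", "malignant"]


@dataclass
class CamResult:
    """Raw, scaled, upsampled and binarized activation maps for one class."""

    raw_map: np.ndarray
    scaled_map: np.ndarray
    upsampled_map: np.ndarray
    binary_map: np.ndarray
    class_index: int
    degenerate: bool


@dataclass
class LocalizationOutcome:
    image_id: str
    true_label: int
    evaluated_class: int
    correct: bool
    overlap_px: int


def compute_cam(feature_maps: np.ndarray, weights: np.ndarray,
                class_index: int) -> np.ndarray:
    """Raw map M_c(i,j) = sum_k w_{k,c} f_k(i,j) at feature resolution."""
    f = np.asarray(feature_maps)
    W = np.asarray(weights)
    if f.ndim != 3 or f.shape[0] != W.shape[0]:
        raise ValueError("feature maps (K,h,w) must match head weights (K,N_c)")
    if not 0 <= class_index < W.shape[1]:
        raise ValueError(f"invalid class index {class_index}")
    return np.tensordot(W[:, class_index], f, axes=([0], [0]))


def scale_cam(raw_map: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min–max scale to [0,1]; a constant map yields zeros + degenerate flag."""
    m = np.asarray(raw_map, dtype=np.float64)
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m), True
    return (m - lo) / (hi - lo), False


def upsample_cam(scaled_map: np.ndarray, target_side: int) -> np.ndarray:
    """Bilinear upsampling to ``target_side``; output clipped to [0,1]."""
    m = np.asarray(scaled_map, dtype=np.float64)
    if target_side < max(m.shape):
        raise ValueError("target resolution below map resolution")
    out = _sk_resize(m, (target_side, target_side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def binarize_cam(upsampled_map: np.ndarray,
                 threshold: float = DEFAULT_CAM_THRESHOLD) -> np.ndarray:
    """Inclusive threshold: a pixel is kept iff its value is >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(upsampled_map) >= threshold


def cam_result(forward: ClassifierForward, weights: np.ndarray,
               class_index: int, target_side: int,
               threshold: float = DEFAULT_CAM_THRESHOLD) -> CamResult:
    """Full CAM chain for one forward pass and class."""
    raw = compute_cam(forward.feature_maps, weights, class_index)
    scaled, degenerate = scale_cam(raw)
    up = upsample_cam(scaled, target_side)
    return CamResult(raw_map=raw, scaled_map=scaled, upsampled_map=up,
                     binary_map=binarize_cam(up, threshold),
                     class_index=class_index, degenerate=degenerate)


def localize(forward: ClassifierForward, weights: np.ndarray,
             gt_mask: np.ndarray, policy: ClassPolicy = "predicted",
             threshold: float = DEFAULT_CAM_THRESHOLD,
             malignant_index: int = 1, true_label: int | None = None,
             image_id: str = "") -> LocalizationOutcome:
    """Score discriminative localization of one image against its annotation.

    The evaluated class follows ``policy``: the predicted class (default),
    the true class, or always the malignant class. Correct iff the binary
    map overlaps the ground-truth mask by >= 1 pixel; a degenerate
    (constant) map binarizes to empty and scores incorrect.
    """
    gt = np.asarray(gt_mask, dtype=bool)
    if not gt.any():
        raise ValueError("empty ground-truth mask")
    if policy == "predicted":
        c = int(np.argmax(forward.probabilities))
    elif policy == "true_class":
        if true_label is None:
            raise ValueError("true_class policy requires true_label")
        c = int(true_label)
    elif policy == "malignant":
        c = malignant_index
    else:
        raise ValueError(f"unknown class policy {policy!r}")
    res = cam_result(forward, weights, c, target_side=gt.shape[0],
                     threshold=threshold)
    overlap = int(np.sum(res.binary_map & gt))
    return LocalizationOutcome(
        image_id=image_id,
        true_label=-1 if true_label is None else int(true_label),
        evaluated_class=c, correct=overlap >= 1, overlap_px=overlap)


def localization_table(outcomes: list[LocalizationOutcome]
                       ) -> ContingencyTable2x2:
    """Correct/incorrect counts by true class (rows benign, malignant)."""
    bc = sum(1 for o in outcomes if o.true_label == 0 and o.correct)
    bi = sum(1 for o in outcomes if o.true_label == 0 and not o.correct)
    mc = sum(1 for o in outcomes if o.true_label == 1 and o.correct)
    mi = sum(1 for o in outcomes if o.true_label == 1 and not o.correct)
    if bc + bi == 0 or mc + mi == 0:
        raise ValueError("outcomes must cover both classes")
    return ContingencyTable2x2(benign_correct=bc, benign_incorrect=bi,
                               malignant_correct=mc, malignant_incorrect=mi)


def tune_threshold(forwards: list[ClassifierForward], weights: np.ndarray,
                   gt_masks: list[np.ndarray],
                   candidates: tuple[float, ...] = tuple(np.round(
                       np.arange(0.1, 0.95, 0.05), 2))) -> float:
    """Optional utility: pick the binarization threshold maximising mean
    Dice overlap between binary CAMs and annotations on a calibration set.

    Not used by the default pipeline, which keeps the fixed 0.3 threshold.
    """
    from .stats import dice_coefficient

    best_t, best_score = candidates[0], -1.0
    for t in candidates:
        scores = []
        for fwd, gt in zip(forwards, gt_masks):
            res = cam_result(fwd, weights, int(np.argmax(fwd.probabilities)),
                             target_side=np.asarray(gt).shape[0], threshold=t)
            if res.binary_map.any() or np.asarray(gt).any():
                scores.append(dice_coefficient(res.binary_map, gt))
        score = float(np.mean(scores)) if scores else 0.0
        if score > best_score:
            best_t, best_score = float(t), score
    return best_t


def save_overlay(pixels: np.ndarray, upsampled_map: np.ndarray,
                 path: str | Path, gt_mask: np.ndarray | None = None) -> None:
    """Write a PNG heat-map composite of an image and its CAM."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3), dpi=100)
    ax.imshow(pixels, cmap="gray", vmin=0, vmax=1)
    ax.imshow(upsampled_map, cmap="jet", alpha=0.35, vmin=0, vmax=1)
    if gt_mask is not None:
        ax.contour(gt_mask, levels=[0.5], colors="w", linewidths=0.8)
    ax.axis("off")
    fig.tight_layout(pad=0)
    fig.savefig(path)
    plt.close(fig)
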