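"""Input preparation: whole-image normalisation and mask-driven ROI cropping.

Two pathways feed the classifiers. The weakly-supervised arm takes the whole
image, resized and max-normalised. The fully-supervised arms crop a square
region of interest around the lesion mask — the mask's bounding box expanded
by a fixed 30-pixel margin, squared symmetrically on the shorter side,
clipped to the image — then resize and normalise the crop identically.

Conventions: 0-based, half-open pixel intervals; bilinear interpolation for
images, nearest for masks; normalisation divides by the post-resize maximum
so the output maximum is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.transform import resize as _sk_resize

Provenance = Literal["whole_image", "roi_manual", "roi_automated"]

DEFAULT_MARGIN = 30


@dataclass
class PreparedInput:
    """A square, max-normalised classifier input."""

    pixels: np.ndarray
    provenance: Provenance
    source_id: str = ""

    def __post_init__(self) -> None:
        h, w = self.pixels.shape
        if h != w:
            raise ValueError("prepared inputs must be square")
        if self.pixels.min() < 0 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("prepared inputs must lie in [0, 1]")


def resize_normalize(pixels: np.ndarray, side: int,
                     provenance: Provenance = "whole_image",
                     source_id: str = "") -> PreparedInput:
    """Bilinear-resize to ``side x side`` then divide by the maximum.

    Raises on an all-zero input, for which max-normalisation is undefined.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.size == 0 or not np.any(pixels):
        raise ValueError("cannot normalise an all-zero image")
    out = _sk_resize(pixels, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    out = np.clip(out, 0.0, None)
    out /= out.max()
    return PreparedInput(pixels=out, provenance=provenance, source_id=source_id)


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tightest half-open box (row_min, row_max, col_min, col_max) of a mask."""
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(rows[0]), int(rows[-1] + 1), int(cols[0]), int(cols[-1] + 1)


def crop_roi(pixels: np.ndarray, mask: np.ndarray, margin: int = DEFAULT_MARGIN,
             side: int = 224, provenance: Provenance = "roi_manual",
             source_id: str = "") -> PreparedInput:
    """Square ROI crop around the mask, margin first, then symmetric squaring.

    The bounding box is expanded by ``margin`` on all four sides, the shorter
    box dimension is grown symmetrically to make the box square, the box is
    clipped to the image bounds (accepting a non-square crop at borders), and
    the crop is resized and max-normalised.
    """
    if pixels.shape != mask.shape:
        raise ValueError("pixels and mask must have the same shape")
    r0, r1, c0, c1 = mask_bbox(mask)
    r0, r1 = r0 - margin, r1 + margin
    c0, c1 = c0 - margin, c1 + margin
    h, w = r1 - r0, c1 - c0
    if h < w:
        pad = w - h
        r0 -= pad // 2
        r1 += pad - pad // 2
    elif w < h:
        pad = h - w
        c0 -= pad // 2
        c1 += pad - pad // 2
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, pixels.shape[0]), min(c1, pixels.shape[1])
    if r1 - r0 < 8 or c1 - c0 < 8:
        raise ValueError("ROI crop degenerated below 8x8 pixels")
    crop = pixels[r0:r1, c0:c1]
    return resize_normalize(crop, side, provenance=provenance,
                            source_id=source_id)


def resize_mask(mask: np.ndarray, side: int) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask (preserves binarity)."""
    out = _sk_resize(mask.astype(np.float64), (side, side), order=0,
                     anti_aliasing=False, preserve_range=True)
    return out > 0.5
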