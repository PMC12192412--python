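"""Morphological cleanup and histogram binarisation.

Erosion and dilation suppress thin eyelashes and small specular highlights
(glints) before circle detection; Otsu's histogram threshold separates the
dark iris disc from the light sclera/skin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from skimage import morphology
from skimage.filters import threshold_otsu

__all__ = [
    "MorphologyConfig",
    "BinaryFrame",
    "erode",
    "dilate",
    "clean",
    "binarise",
]


@dataclass(frozen=True)
class MorphologyConfig:
    """Structuring element and iteration counts for grayscale morphology.

    Defaults: 3x3 ellipse, one erosion then one dilation — an opening of the
    brightness signal, which absorbs small bright glints while leaving large
    dark structures (the iris) intact.
    """

    kernel_shape: Literal["ellipse", "rect", "cross"] = "ellipse"
    kernel_size: int = 3
    erode_iterations: int = 1
    dilate_iterations: int = 1
    order: Literal["erode_first", "dilate_first"] = "erode_first"

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.erode_iterations < 0 or self.dilate_iterations < 0:
            raise ValueError("iteration counts must be non-negative")

    def footprint(self) -> np.ndarray:
        k = self.kernel_size
        if self.kernel_shape == "rect":
            return np.ones((k, k), dtype=bool)
        if self.kernel_shape == "cross":
            fp = np.zeros((k, k), dtype=bool)
            fp[k // 2, :] = True
            fp[:, k // 2] = True
            return fp
        if self.kernel_shape == "ellipse":
            # disc inscribed in a k x k window
            r = k // 2
            yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
            return (xx * xx + yy * yy) <= r * r
        raise ValueError(f"unknown kernel shape {self.kernel_shape!r}")


@dataclass
class BinaryFrame:
    """0/255 mask plus the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float
    degenerate: bool = False


def erode(img: np.ndarray, cfg: MorphologyConfig) -> np.ndarray:
    """Structuring-element minimum, applied ``erode_iterations`` times."""
    out = np.asarray(img)
    fp = cfg.footprint()
    for _ in range(cfg.erode_iterations):
        out = morphology.erosion(out, fp)
    return out


def dilate(img: np.ndarray, cfg: MorphologyConfig) -> np.ndarray:
    """Structuring-element maximum, applied ``dilate_iterations`` times."""
    out = np.asarray(img)
    fp = cfg.footprint()
    for _ in range(cfg.dilate_iterations):
        out = morphology.dilation(out, fp)
    return out


def clean(img: np.ndarray, cfg: Optional[MorphologyConfig] = None) -> np.ndarray:
    """Apply the erosion/dilation pair in the configured order."""
    cfg = cfg or MorphologyConfig()
    if cfg.order == "erode_first":
        return dilate(erode(img, cfg), cfg)
    return erode(dilate(img, cfg), cfg)


def binarise(img: np.ndarray, threshold: Optional[float] = None) -> BinaryFrame:
    """Histogram-based binarisation: pixels >= threshold become 255 (white).

    The threshold defaults to Otsu's between-class-variance maximiser; pass
    ``threshold`` for a fixed value.  A constant image cannot be split and
    yields an all-zero mask flagged degenerate.
    """
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("cannot binarise an empty image")
    lo, hi = arr.min(), arr.max()
    if lo == hi:
        return BinaryFrame(
            mask=np.zeros_like(arr, dtype=np.uint8),
            threshold_used=float(lo),
            degenerate=True,
        )
    if threshold is None:
        # threshold_otsu marks foreground as img > t; shift t to the midpoint
        # of the gap above it so the ">= threshold" convention is equivalent
        t = float(threshold_otsu(arr))
        vals = np.unique(arr)
        above = vals[vals > t]
        below = vals[vals <= t]
        if above.size and below.size:
            threshold = (float(below.max()) + float(above.min())) / 2.0
        else:
            threshold = t
    mask = np.where(arr >= threshold, 255, 0).astype(np.uint8)
    return BinaryFrame(mask=mask, threshold_used=float(threshold))
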