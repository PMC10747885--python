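"""Canopy segmentation: crop → grayscale → global OTSU → morphological cleanup.

The nadir RGB frames mix bright leaf pixels with darker soil, shaded
regions and bed edges.  Segmentation is deliberately classical: a global
OTSU threshold on the grayscale image separates leaf from ground, and a
morphological closing followed by an erosion (3×3 square elements)
removes the speckle left by slim stems and soil showing through canopy
holes.  The known failure mode — heavily shaded leaves falling below the
threshold — is kept observable rather than patched over.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .core import (
    CanopyMask,
    ConfigError,
    CropWindow,
    DegenerateImageError,
    Scan,
    _copy_scan,
)

__all__ = [
    "REC601_WEIGHTS",
    "crop",
    "to_grayscale",
    "otsu_threshold",
    "binarize",
    "clean_mask",
    "render_mask",
    "segment_scan",
]

#: Rec. 601 luma weights (R, G, B).
REC601_WEIGHTS = (0.299, 0.587, 0.114)

_STRUCT3 = np.ones((3, 3), dtype=bool)


def crop(scan: Scan, window: CropWindow) -> Scan:
    """Remove boundary margins from RGB and disparity identically.

    Pixel coordinates in the result are re-based to the cropped origin.
    Raises :class:`ConfigError` if the window leaves no interior.
    """
    h, w = scan.shape
    window.apply_shape((h, w))  # raises if exhausted
    rs = slice(window.top, h - window.bottom)
    cs = slice(window.left, w - window.right)
    return _copy_scan(scan, rgb=scan.rgb[rs, cs], disparity=scan.disparity[rs, cs])


def to_grayscale(rgb: np.ndarray, weights=REC601_WEIGHTS) -> np.ndarray:
    """8-bit luma from an 8-bit RGB grid (Rec. 601 weights, rounded)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ConfigError("expected an (H, W, 3) RGB array")
    gray = rgb.astype(float) @ np.asarray(weights, dtype=float)
    return np.rint(gray).clip(0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Global OTSU threshold of an 8-bit image.

    Returns the grey level ``t`` maximising the between-class variance of
    the 256-bin histogram, classes being ``<= t`` and ``> t``; ties break
    to the smallest ``t``.  A constant image is degenerate (one class)
    and raises :class:`DegenerateImageError`.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise DegenerateImageError("empty image")
    counts = np.bincount(gray.astype(np.uint8).ravel(), minlength=256)
    if np.count_nonzero(counts) < 2:
        raise DegenerateImageError("constant image: OTSU is undefined")
    t = threshold_otsu(hist=(counts, np.arange(256)))
    return int(t)


def binarize(gray: np.ndarray, threshold: int, invert: bool = False) -> np.ndarray:
    """Foreground map from a threshold.

    Default polarity takes the brighter class (``> threshold``) as leaf —
    daylight canopies are brighter than soil; ``invert=True`` flips it.
    """
    fg = np.asarray(gray) > threshold
    return ~fg if invert else fg


def clean_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Morphological closing then erosion with 3×3 square elements.

    Closing (dilation then erosion) fills pinholes; the trailing erosion
    strips isolated speckle and thin bridges.  Out-of-image pixels count
    as background for every operation, and each pass runs ``iterations``
    times.  The output never gains foreground outside the dilation
    envelope of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if iterations < 1:
        return mask.copy()
    out = mask
    for _ in range(iterations):
        dil = ndi.binary_dilation(out, structure=_STRUCT3, border_value=0)
        out = ndi.binary_erosion(dil, structure=_STRUCT3, border_value=0)
    for _ in range(iterations):
        out = ndi.binary_erosion(out, structure=_STRUCT3, border_value=0)
    return out


def render_mask(mask: np.ndarray) -> np.ndarray:
    """Black/white rendering: foreground 255, background 0 (uint8)."""
    return np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)


def segment_scan(
    scan: Scan,
    window: CropWindow = CropWindow(),
    invert: bool = False,
    iterations: int = 1,
) -> tuple[CanopyMask, Scan]:
    """Full segmentation of one scan.

    Crops, converts to grayscale, thresholds with OTSU, cleans the mask.
    Returns the mask together with the cropped scan (whose disparity grid
    the height stage aligns with the mask coordinates).
    """
    cropped = crop(scan, window)
    gray = to_grayscale(cropped.rgb)
    t = otsu_threshold(gray)
    raw = binarize(gray, t, invert=invert)
    cleaned = clean_mask(raw, iterations=iterations)
    return CanopyMask(mask=cleaned, threshold_used=t), cropped
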