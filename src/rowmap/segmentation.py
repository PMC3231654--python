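"""Vegetation segmentation of field frames.

Vegetation pixels carry a much stronger green component than soil, so a
linear greenness index gray = r*R + g*G + b*B (with coefficients tuned for
crop/soil discrimination, defaults r=-0.884, g=1.262, b=-0.311) turns an
RGB frame into a grayscale image in which plants are bright and soil is
dark.  Otsu thresholding then yields a binary vegetation mask, and a
morphological opening with slightly vertical rectangular structuring
elements (erode 10x15, dilate 10x20, width x height) removes small weed
blobs while keeping the vertically continuous crop rows.

Only the lower half of the frame is processed: near the top of a frame
taken from a tractor-mounted, downward-pitched camera the rows crowd
together under perspective and stop being separable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class SegCoefficients:
    """Greenness-index weights for the red, green and blue planes."""

    r: float = -0.884
    g: float = 1.262
    b: float = -0.311

    def __post_init__(self) -> None:
        for v in (self.r, self.g, self.b):
            if not np.isfinite(v):
                raise ValueError("coefficients must be finite")


DEFAULT_COEFFICIENTS = SegCoefficients()

# structuring elements as (height, width); anchors at (h//2, w//2), which is
# scipy.ndimage's own convention for even sizes (verified against a window
# sweep in the tests)
ERODE_SIZE = (15, 10)
DILATE_SIZE = (20, 10)


def crop_lower_half(frame: np.ndarray) -> np.ndarray:
    """Keep the bottom floor(h/2) rows of a frame (720x576 -> 720x288).

    The rule is the same for odd heights: a 575-row frame keeps its bottom
    287 rows.
    """
    f = np.asarray(frame)
    if f.ndim < 2 or f.shape[0] < 2 or f.shape[1] == 0:
        raise ValueError("frame must have at least 2 rows and 1 column")
    return f[f.shape[0] - f.shape[0] // 2 :]


def rgb_to_gray(
    frame: np.ndarray, coeffs: SegCoefficients = DEFAULT_COEFFICIENTS
) -> np.ndarray:
    """Greenness index image, clamped to [0, 255].

    The linear combination can leave the byte range (pure green maps to
    1.262*255 = 321.8; pure red to -225.4), so the result is clamped before
    thresholding, as is standard for greenness indices.
    """
    f = np.asarray(frame, dtype=float)
    if f.ndim != 3 or f.shape[2] != 3:
        raise ValueError("frame must be h x w x 3 RGB")
    gray = coeffs.r * f[..., 0] + coeffs.g * f[..., 1] + coeffs.b * f[..., 2]
    return np.clip(gray, 0.0, 255.0)


def binarize(gray: np.ndarray) -> np.ndarray:
    """Per-frame automatic threshold (Otsu); pixels above it become 1.

    Otsu's between-class-variance criterion adapts the cut to each frame's
    lighting; a constant image has no foreground and yields an all-zero mask.
    """
    g = np.asarray(gray, dtype=float)
    if g.min() == g.max():
        return np.zeros(g.shape, dtype=np.uint8)
    t = threshold_otsu(g)
    return (g > t).astype(np.uint8)


def _binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    return m.astype(bool)


def erode_mask(mask: np.ndarray, size: tuple[int, int] = ERODE_SIZE) -> np.ndarray:
    """Binary erosion with a rectangular element; borders padded with background."""
    return ndimage.binary_erosion(
        _binary(mask), structure=np.ones(size, bool), border_value=0
    ).astype(np.uint8)


def dilate_mask(mask: np.ndarray, size: tuple[int, int] = DILATE_SIZE) -> np.ndarray:
    """Binary dilation with a rectangular element; background outside borders."""
    return ndimage.binary_dilation(
        _binary(mask), structure=np.ones(size, bool), border_value=0
    ).astype(np.uint8)


def open_for_rows(
    mask: np.ndarray,
    erode_size: tuple[int, int] = ERODE_SIZE,
    dilate_size: tuple[int, int] = DILATE_SIZE,
) -> np.ndarray:
    """Morphological opening that removes weed blobs and solidifies rows.

    Erosion with the 10-wide x 15-tall rectangle deletes any foreground
    region that cannot contain the element (so blobs strictly smaller than
    10 x 15 vanish); the following dilation with the taller 10 x 20 rectangle
    thickens the surviving rows vertically and closes sowing-gap breaks.
    """
    return dilate_mask(erode_mask(mask, erode_size), dilate_size)


def segment_frame(
    frame: np.ndarray,
    coeffs: SegCoefficients = DEFAULT_COEFFICIENTS,
    erode_size: tuple[int, int] = ERODE_SIZE,
    dilate_size: tuple[int, int] = DILATE_SIZE,
) -> np.ndarray:
    """Full segmentation chain: crop lower half, greenness, Otsu, opening."""
    return open_for_rows(
        binarize(rgb_to_gray(crop_lower_half(frame), coeffs)),
        erode_size,
        dilate_size,
    )
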