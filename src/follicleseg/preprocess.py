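"""Ultrasound image enhancement chain.

Transvaginal B-mode images are low-contrast and corrupted by multiplicative
speckle; follicle walls can sit at nearly the same gray level as the follicle
lumen.  The enhancement chain applied before segmentation is:

    contrast stretch  ->  5x5 median despeckling  ->  histogram equalization

Every stage maps 8-bit images to 8-bit images of the same shape, and every
stage is monotone (order-preserving) on pixel values.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

logger = logging.getLogger("follicleseg.preprocess")

__all__ = [
    "to_grayscale",
    "intensity_transform",
    "median_filter5",
    "hist_equalize",
    "preprocess",
]

#: Rec. 601 luma weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def _check_uint8(img: np.ndarray, op: str) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{op}: expected a 2-D grayscale image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError(f"{op}: empty image")
    return img.astype(np.uint8, copy=False)


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to grayscale by Rec. 601 luma weighting.

    luma = round(0.299 R + 0.587 G + 0.114 B), clipped to [0, 255].
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"to_grayscale: expected H x W x 3 input, got shape {rgb.shape}")
    wr, wg, wb = LUMA_WEIGHTS
    y = wr * rgb[..., 0].astype(np.float64) + wg * rgb[..., 1] + wb * rgb[..., 2]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def intensity_transform(
    img: np.ndarray, low_frac: float = 0.01, high_frac: float = 0.99
) -> np.ndarray:
    """Linear contrast stretch between two cumulative-histogram bounds.

    The lower bound L is the smallest gray level whose cumulative histogram
    fraction exceeds ``low_frac``; the upper bound U is the smallest level
    whose fraction reaches ``high_frac``.  Pixels are mapped affinely so L -> 0
    and U -> 255, with saturation (clipping) outside [L, U].  Defaults saturate
    roughly 1% of pixels at each tail.

    A near-constant image (U == L) is returned unchanged with a warning.
    """
    img = _check_uint8(img, "intensity_transform")
    if not (0.0 <= low_frac < high_frac <= 1.0):
        raise ValueError(
            f"intensity_transform: need 0 <= low_frac < high_frac <= 1, "
            f"got ({low_frac}, {high_frac})"
        )
    counts = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(counts) / img.size
    lower = int(np.argmax(cdf > low_frac))
    upper = int(np.argmax(cdf >= high_frac))
    if upper == lower:
        logger.warning(
            "intensity_transform: degenerate bounds L == U == %d; image unchanged", lower
        )
        return img.copy()
    scaled = (img.astype(np.float64) - lower) / (upper - lower)
    return np.rint(255.0 * np.clip(scaled, 0.0, 1.0)).astype(np.uint8)


def median_filter5(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Median despeckling over a ``window`` x ``window`` neighborhood.

    Each pixel is replaced by the middle value of the sorted neighborhood.
    Borders use reflect padding so follicles touching the frame are not
    darkened.  ``window`` must be odd and >= 3.
    """
    img = _check_uint8(img, "median_filter5")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"median_filter5: window must be odd and >= 3, got {window}")
    return ndimage.median_filter(img, size=window, mode="reflect")


def hist_equalize(img: np.ndarray) -> np.ndarray:
    """Histogram equalization over 256 bins.

    With cdf(v) the fraction of pixels <= v and cdf_min the cdf at the lowest
    occupied bin, each level maps to

        round(255 * (cdf(v) - cdf_min) / (1 - cdf_min)).

    The map is monotone non-decreasing; a constant image (cdf_min == 1)
    collapses to all zeros with a warning.
    """
    img = _check_uint8(img, "hist_equalize")
    counts = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(counts) / img.size
    cdf_min = cdf[np.argmax(counts > 0)]
    if cdf_min >= 1.0:
        logger.warning("hist_equalize: constant image; output is all zeros")
        return np.zeros_like(img)
    lut = np.rint(255.0 * (cdf - cdf_min) / (1.0 - cdf_min)).astype(np.uint8)
    return lut[img]


def preprocess(
    img: np.ndarray,
    low_frac: float = 0.01,
    high_frac: float = 0.99,
    median_window: int = 5,
    equalize: bool = True,
) -> np.ndarray:
    """Full enhancement chain: contrast stretch, median filter, equalization."""
    out = intensity_transform(img, low_frac=low_frac, high_frac=high_frac)
    out = median_filter5(out, window=median_window)
    if equalize:
        out = hist_equalize(out)
    return out
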