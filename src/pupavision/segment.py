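"""Pupal region extraction from the saturation channel.

The pupal case is strongly colored while the background is near-neutral, so
the saturation image is close to bimodal. Otsu's threshold separates the two
modes; the bright (high-S) side is the pupa. Interior holes are filled,
speckle and thin protrusions are removed by a morphological opening, and the
largest connected component is kept as the pupal region.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label
from skimage.morphology import disk

from pupavision.preprocess import SaturationChannel


class SegmentationError(RuntimeError):
    """Raised when no pupal region can be extracted from an image."""

    def __init__(self, message: str, pupa_id: str = "", day_index: int | None = None):
        self.pupa_id = pupa_id
        self.day_index = day_index
        ctx = f" (pupa_id={pupa_id!r}, day={day_index})" if pupa_id or day_index else ""
        super().__init__(message + ctx)


def otsu_threshold(s: SaturationChannel | np.ndarray) -> int:
    """Otsu threshold of an 8-bit image over its 256-bin histogram.

    Returns the threshold ``t`` in [0, 254] maximizing the between-class
    variance of the split into classes {p <= t} and {p > t}; ties are broken
    by the smallest ``t``. A constant image has no valid split and raises.
    """
    px = np.asarray(s.pixels if isinstance(s, SaturationChannel) else s)
    if px.dtype != np.uint8:
        if px.min() < 0 or px.max() > 255:
            raise ValueError("expected gray levels in [0, 255]")
        px = px.astype(np.uint8)
    hist = np.bincount(px.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 distinct gray levels")
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # count of pixels <= t
    m0 = np.cumsum(hist * levels)  # sum of levels <= t
    total = m0[-1]
    # valid split points: both classes non-empty
    valid = (w0 > 0) & (w0 < n)
    w0f = w0 / n
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=w0 > 0)
    mu1 = np.divide(total - m0, n - w0, out=np.zeros_like(m0), where=(n - w0) > 0)
    sigma_b = w0f * (1.0 - w0f) * (mu0 - mu1) ** 2
    sigma_b[~valid] = -1.0
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def binarize(s: SaturationChannel | np.ndarray, t: int) -> np.ndarray:
    """Boolean mask of the bright (high-saturation) side: pixels > t."""
    px = np.asarray(s.pixels if isinstance(s, SaturationChannel) else s)
    return px > t


def fill_holes(m: np.ndarray) -> np.ndarray:
    """Set every background component not connected to the image border to foreground."""
    return ndi.binary_fill_holes(np.asarray(m, dtype=bool))


def open_morphological(m: np.ndarray, radius: int = 5) -> np.ndarray:
    """Morphological opening (erosion then dilation) with a disk of the given radius."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return ndi.binary_opening(np.asarray(m, dtype=bool), structure=disk(radius))


def extract_pupa_region(m: np.ndarray, pupa_id: str = "", day_index: int | None = None) -> np.ndarray:
    """Keep the largest 8-connected foreground component (holes re-filled).

    Raises :class:`SegmentationError` when the mask is empty.
    """
    m = np.asarray(m, dtype=bool)
    lab, n = label(m, connectivity=2, return_num=True)
    if n == 0:
        raise SegmentationError("empty mask: no foreground component", pupa_id, day_index)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    keep = lab == int(np.argmax(counts))
    return fill_holes(keep)


def segment_pupa(
    s: SaturationChannel | np.ndarray,
    opening_radius: int = 5,
    pupa_id: str = "",
    day_index: int | None = None,
) -> np.ndarray:
    """Full segmentation chain: Otsu -> binarize -> fill holes -> open -> largest component."""
    try:
        t = otsu_threshold(s)
    except ValueError as exc:
        raise SegmentationError(str(exc), pupa_id, day_index) from exc
    m = binarize(s, t)
    m = fill_holes(m)
    m = open_morphological(m, opening_radius)
    return extract_pupa_region(m, pupa_id, day_index)
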