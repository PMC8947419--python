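"""Range normalization and color-space conversion.

The acquisition system writes 3-channel TIFFs whose pixels span [0, 65520].
Downstream stages work on 8-bit data, so the first step maps the wide range
onto [0, 255] (round half up). Gray conversion of the raw color frames gives
poor pupa/background contrast; the saturation (S) channel of the HSV
representation separates the strongly colored pupal case from the neutral
background much more cleanly, so segmentation operates on S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb

RAW_MAX = 65520
"""Upper end of the raw pixel range produced by the acquisition software."""


def round_half_up(x):
    """Round half away from zero toward +inf, elementwise (ties like 0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass
class RawPupaImage:
    """One 3-channel wide-range image of a single pupa on one day.

    Parameters
    ----------
    pixels : (H, W, 3) integer array with values in [0, 65520].
    pupa_id : identifier of the pupa.
    day_index : 1-based day of the series (day 1 = newly pupated).
    water_treated_day8 : whether the pupa had received the day-8 water
        immersion at capture time (metadata only; no optical effect is
        modeled).
    """

    pixels: np.ndarray
    pupa_id: str = ""
    day_index: int = 1
    water_treated_day8: bool = False

    def validate(self) -> "RawPupaImage":
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected a 3-channel image, got shape {px.shape}")
        mn, mx = int(px.min()), int(px.max())
        if mn < 0:
            raise ValueError(f"pixel minimum {mn} below 0")
        if mx > RAW_MAX:
            raise ValueError(f"pixel maximum {mx} exceeds {RAW_MAX}")
        return self


@dataclass
class Normalized8bitImage:
    """3-channel image mapped onto [0, 255], with provenance."""

    pixels: np.ndarray
    pupa_id: str = ""
    day_index: int = 1
    water_treated_day8: bool = False


@dataclass
class SaturationChannel:
    """Single-channel HSV saturation image on the [0, 255] integer scale."""

    pixels: np.ndarray
    pupa_id: str = ""
    day_index: int = 1


_LUT_CACHE: dict = {}


def _range_lut(in_max: int, out_max: int) -> np.ndarray:
    key = (in_max, out_max)
    lut = _LUT_CACHE.get(key)
    if lut is None:
        lut = round_half_up(np.arange(in_max + 1, dtype=np.float64) * (out_max / in_max))
        lut = lut.astype(np.uint8 if out_max <= 255 else np.uint16)
        _LUT_CACHE[key] = lut
    return lut


def normalize_range(img: RawPupaImage, in_max: int = RAW_MAX, out_max: int = 255) -> Normalized8bitImage:
    """Map pixels from [0, in_max] onto [0, out_max] with round-half-up.

    The map is monotone and preserves both endpoints (0 -> 0,
    in_max -> out_max). Pixels above ``in_max`` are a validation error.
    """
    if in_max <= 0:
        raise ValueError("in_max must be positive")
    px = np.asarray(img.pixels)
    mx = int(px.max()) if px.size else 0
    if mx > in_max:
        raise ValueError(f"pixel maximum {mx} exceeds declared in_max {in_max}")
    if int(px.min()) < 0:
        raise ValueError("negative pixel values")
    if np.issubdtype(px.dtype, np.integer):
        out = _range_lut(in_max, out_max)[px]
        return Normalized8bitImage(
            pixels=out,
            pupa_id=img.pupa_id,
            day_index=img.day_index,
            water_treated_day8=img.water_treated_day8,
        )
    out = round_half_up(px.astype(np.float64) * (out_max / in_max))
    dtype = np.uint8 if out_max <= 255 else np.uint16
    return Normalized8bitImage(
        pixels=out.astype(dtype),
        pupa_id=img.pupa_id,
        day_index=img.day_index,
        water_treated_day8=img.water_treated_day8,
    )


def to_hsv(img: Normalized8bitImage, compute_hue: bool = True):
    """Convert an 8-bit RGB image to (H, S, V).

    Returns
    -------
    H : float array on a [0, 255] scale (hue 0-360 deg mapped linearly onto
        0-255; unused downstream, kept for completeness), or None when
        ``compute_hue`` is False.
    S : :class:`SaturationChannel`, uint8. S = (max-min)/max per pixel
        (0 where max = 0), scaled to [0, 255] with round-half-up.
    V : uint8 array, the per-pixel channel maximum.
    """
    px = np.asarray(img.pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {px.shape}")
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = (mx - mn).astype(np.float64)
    mxf = mx.astype(np.float64)
    s_frac = np.where(mx > 0, delta / np.where(mx > 0, mxf, 1.0), 0.0)
    s = np.floor(s_frac * 255.0 + 0.5).astype(np.uint8)
    v = mx.astype(np.uint8)
    h = None
    if compute_hue:
        rf, gf, bf = (c.astype(np.float64) for c in (r, g, b))
        safe_d = np.where(delta > 0, delta, 1.0)
        h6 = np.where(
            mx == r,
            ((gf - bf) / safe_d) % 6.0,
            np.where(mx == g, (bf - rf) / safe_d + 2.0, (rf - gf) / safe_d + 4.0),
        )
        h6 = np.where(delta > 0, h6, 0.0)
        h = h6 / 6.0 * 255.0
    return h, SaturationChannel(pixels=s, pupa_id=img.pupa_id, day_index=img.day_index), v


def hsv_to_rgb8(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_hsv` (all inputs on the [0, 255] scale)."""
    hsv = np.stack(
        [
            np.asarray(h, dtype=np.float64) / 255.0,
            np.asarray(s, dtype=np.float64) / 255.0,
            np.asarray(v, dtype=np.float64) / 255.0,
        ],
        axis=-1,
    )
    return round_half_up(hsv2rgb(hsv) * 255.0).astype(np.uint8)


def to_gray(img: Normalized8bitImage) -> np.ndarray:
    """Luminance grayscale (float, [0, 255]) of an 8-bit RGB image."""
    from skimage.color import rgb2gray

    return rgb2gray(np.asarray(img.pixels)) * 255.0
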