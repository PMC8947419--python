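"""Pectinate-setae stripe detection in the tail cell and the sex call.

Male pupae carry long pectinate setae (0.05-0.18 mm) on the tail about two
days before eclosion; short setae (0.02-0.05 mm) occur in both sexes. In the
standardized frame the setae appear as short dark stripes roughly
perpendicular to the body axis. Detection thresholds the cell at
``mean - dark_k * std``, keeps elongated components oriented near vertical,
and measures each stripe's physical length using the per-axis calibration
carried through the anisotropic resize. A pupa is called male as soon as any
day shows at least ``min_long_count`` stripes strictly longer than the
0.05 mm boundary.

Stripe length is measured as the center-to-center extent, along the
component's principal axis, of the pixels at or below half stripe depth
(halfway between the cell mean and the stripe's darkest level). This FWHM-style
measure ignores the blurred anti-aliased tips, so it reads slightly short
(about one raw pixel); borderline short setae are therefore never promoted
over the male decision boundary by interpolation blur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops


@dataclass
class ClassifierParams:
    """Decision parameters for stripe detection and the sex call.

    long_threshold_mm : stripes strictly longer than this are "long"
        (male-only); the 0.05 mm boundary itself counts as short.
    min_long_count : number of long stripes required for a male call.
    elongation_min : minimum major/minor axis ratio of a component.
    orientation_band_deg : allowed deviation of the stripe axis from the
        vertical (perpendicular to the body axis) direction.
    dark_k : multiplier on the cell standard deviation for the dark
        threshold ``mean - dark_k * std``.
    min_area_px : minimum component area in standardized pixels (speckle
        guard).
    """

    long_threshold_mm: float = 0.05
    min_long_count: int = 1
    elongation_min: float = 3.0
    orientation_band_deg: float = 30.0
    dark_k: float = 2.0
    min_area_px: int = 20

    def __post_init__(self):
        if not (0.0 < self.long_threshold_mm <= 0.18):
            raise ValueError("long_threshold_mm must be in (0, 0.18]")
        if self.min_long_count < 1:
            raise ValueError("min_long_count must be >= 1")


@dataclass
class Stripe:
    """One detected dark elongated component (candidate seta)."""

    cell_index: int
    centroid: tuple[float, float]  # (x, y) in cell pixels
    length_px: float
    length_mm: float
    orientation_deg: float  # versus horizontal, in (-90, 90]
    mean_darkness: float  # cell mean minus component mean gray


@dataclass
class SetaeCall:
    """Per-image (one pupa, one day) detection outcome."""

    pupa_id: str
    day_index: int
    stripes: list = field(default_factory=list)
    long_stripe_count: int = 0
    call: str = "no_setae_detected"  # or "male_setae_detected"


@dataclass
class PupaCall:
    """Pupa-level latch over the day series."""

    pupa_id: str
    positive: bool
    first_positive_day: int | None = None


def _principal_axis(coords_rc: np.ndarray):
    """Unit principal axis (row, col) and sqrt-eigenvalue elongation of pixel coords."""
    c = coords_rc - coords_rc.mean(axis=0)
    cov = c.T @ c / len(c)
    vals, vecs = np.linalg.eigh(cov)
    lam2, lam1 = float(vals[0]), float(vals[1])
    axis = vecs[:, 1]
    elong = np.inf if lam2 <= 1e-12 else np.sqrt(lam1 / lam2)
    return axis, elong


def detect_stripes(
    cell: np.ndarray,
    um_per_px_std: tuple[float, float],
    params: ClassifierParams = ClassifierParams(),
    cell_index: int = 0,
) -> list[Stripe]:
    """Detect dark elongated stripes in one standardized grid cell.

    Dark pixels are those below ``mean - dark_k * std`` of the cell.
    8-connected components are filtered by area, elongation and orientation;
    survivors are reported as :class:`Stripe` records with physical lengths
    computed from the per-axis calibration projected onto the stripe axis.
    """
    arr = np.asarray(cell, dtype=np.float64)
    cal_x, cal_y = um_per_px_std
    if cal_x <= 0 or cal_y <= 0:
        raise ValueError("calibration must be positive")
    mean = arr.mean()
    thr = mean - params.dark_k * arr.std()
    dark = arr < thr
    if not dark.any():
        return []
    # The loose threshold sits just under the cell mean, so each stripe comes
    # with a wide interpolation skirt that can chain neighboring setae into a
    # single component. Each component is therefore reduced to its half-depth
    # core (pixels at or below halfway between the cell mean and the
    # component's darkest level) and the core blobs are re-labeled and
    # measured individually.
    lab = label(dark, connectivity=2)
    core_mask = np.zeros_like(dark)
    for region in regionprops(lab, intensity_image=arr):
        core_level = 0.5 * (mean + region.intensity_min)
        rr, cc = region.coords.T
        sel = arr[rr, cc] <= core_level
        core_mask[rr[sel], cc[sel]] = True
    stripes: list[Stripe] = []
    for region in regionprops(label(core_mask, connectivity=2), intensity_image=arr):
        if region.area < params.min_area_px:
            continue
        coords = region.coords.astype(np.float64)
        axis, elong = _principal_axis(coords)
        if elong < params.elongation_min:
            continue
        er, ec = float(axis[0]), float(axis[1])
        # deviation of the stripe axis from vertical (the row direction)
        dev = np.degrees(np.arctan2(abs(ec), abs(er)))
        if dev > params.orientation_band_deg:
            continue
        proj = coords @ np.array([er, ec])
        length_px = float(proj.max() - proj.min())
        length_mm = length_px * np.hypot(ec * cal_x, er * cal_y) / 1000.0
        if length_mm <= 0:
            continue
        theta = float(np.degrees(np.arctan2(er, ec)))
        if theta <= -90.0:
            theta += 180.0
        elif theta > 90.0:
            theta -= 180.0
        cy, cx = region.centroid
        vals = arr[tuple(region.coords.T)]
        stripes.append(
            Stripe(
                cell_index=cell_index,
                centroid=(float(cx), float(cy)),
                length_px=length_px,
                length_mm=float(length_mm),
                orientation_deg=theta,
                mean_darkness=float(mean - vals.mean()),
            )
        )
    return stripes


def call_sex(
    stripes: list[Stripe],
    params: ClassifierParams = ClassifierParams(),
    pupa_id: str = "",
    day_index: int = 1,
) -> SetaeCall:
    """Daily call: male iff >= min_long_count stripes strictly longer than the boundary."""
    n_long = sum(1 for s in stripes if s.length_mm > params.long_threshold_mm)
    call = "male_setae_detected" if n_long >= params.min_long_count else "no_setae_detected"
    return SetaeCall(
        pupa_id=pupa_id,
        day_index=day_index,
        stripes=list(stripes),
        long_stripe_count=n_long,
        call=call,
    )


def call_pupa(daily_calls: list[SetaeCall]) -> PupaCall:
    """Latch rule over the series: positive iff any day is positive."""
    if not daily_calls:
        raise ValueError("need at least one daily call")
    calls = sorted(daily_calls, key=lambda c: c.day_index)
    pid = calls[0].pupa_id
    for c in calls:
        if c.call == "male_setae_detected":
            return PupaCall(pupa_id=pid, positive=True, first_positive_day=c.day_index)
    return PupaCall(pupa_id=pid, positive=False, first_positive_day=None)
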