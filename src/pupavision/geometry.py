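"""Pose normalization: minimum enclosing ellipse -> rectangle -> straighten -> crop -> resize.

The pupal body is close to elliptical, so the minimum-area enclosing ellipse
of the segmented region gives a robust estimate of the body axis even when the
mask boundary is noisy. The rotated rectangle circumscribing that ellipse
(width = major diameter, height = minor diameter) supplies the rotation angle;
the image is rotated so the body axis is horizontal, cropped to the rectangle,
and resized to a fixed 2800x1300 frame. The anisotropic resize is compensated
by carrying a per-axis physical calibration (um per standardized pixel) so
lengths measured downstream stay physical.

Coordinates are 0-based with the origin at the top-left corner, x = column,
y = row (y increases downward); rectangle bounds are half-open. Angles are in
degrees in (-90, 90], measured from the +x axis in this image frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.transform import AffineTransform, resize, warp

STD_WIDTH = 2800
STD_HEIGHT = 1300


class DegenerateGeometryError(RuntimeError):
    """Raised when a mask is too small or degenerate for ellipse fitting."""


@dataclass
class EnclosingEllipse:
    """Minimum-area enclosing ellipse of a foreground region.

    center : (x, y) in pixels; semi_major >= semi_minor > 0 in pixels;
    angle_deg : major-axis angle versus the image x-axis, in (-90, 90].
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle_deg: float

    def contains(self, points_xy: np.ndarray, tol: float = 0.5) -> bool:
        """Whether all (x, y) points lie inside or on the ellipse within tol pixels."""
        q = self._quadratic_form(points_xy)
        # allow tol px of slack along the tighter axis
        slack = tol / max(self.semi_minor, 1e-9)
        return bool(np.all(np.sqrt(np.maximum(q, 0.0)) <= 1.0 + slack))

    def boundary_points(self, n: int = 360) -> np.ndarray:
        """(n, 2) array of (x, y) points sampled on the ellipse boundary."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        th = np.deg2rad(self.angle_deg)
        x = self.semi_major * np.cos(t)
        y = self.semi_minor * np.sin(t)
        c, s = np.cos(th), np.sin(th)
        return np.column_stack(
            [self.center[0] + c * x - s * y, self.center[1] + s * x + c * y]
        )

    def _quadratic_form(self, points_xy: np.ndarray) -> np.ndarray:
        p = np.asarray(points_xy, dtype=np.float64) - np.asarray(self.center)
        th = np.deg2rad(self.angle_deg)
        c, s = np.cos(th), np.sin(th)
        u = (p[:, 0] * c + p[:, 1] * s) / self.semi_major
        v = (-p[:, 0] * s + p[:, 1] * c) / self.semi_minor
        return u * u + v * v


@dataclass
class EnclosingRect:
    """Rotated rectangle: center (x, y), width >= height, angle as the ellipse."""

    center: tuple[float, float]
    width: float
    height: float
    angle_deg: float


@dataclass
class StandardPupaImage:
    """Straightened, cropped image resized to the standard 2800x1300 frame.

    pixels : (1300, 2800) float grayscale on the [0, 255] scale.
    color : optional (1300, 2800, 3) color companion (may be None).
    um_per_px_std : (x, y) physical calibration of standardized pixels, in
        micrometres per pixel, after the anisotropic resize.
    """

    pixels: np.ndarray
    um_per_px_std: tuple[float, float]
    pupa_id: str = ""
    day_index: int = 1
    color: np.ndarray | None = None

    def __post_init__(self):
        h, w = self.pixels.shape[:2]
        if (w, h) != (STD_WIDTH, STD_HEIGHT):
            raise ValueError(f"standard image must be {STD_WIDTH}x{STD_HEIGHT}, got {w}x{h}")


def _mvee(points: np.ndarray, tol: float = 1e-3, max_iter: int = 2000):
    """Khachiyan's algorithm for the minimum-volume enclosing ellipsoid.

    Returns (center, A) with the ellipse {p : (p-c)^T A (p-c) <= 1}.
    Converges linearly; iteration stops at a relative duality gap of ``tol``
    or when the weight update stalls.
    """
    pts = np.asarray(points, dtype=np.float64)
    n, d = pts.shape
    Q = np.column_stack([pts, np.ones(n)])  # (n, d+1)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q.T @ (u[:, None] * Q)  # (d+1, d+1)
        try:
            Xi = np.linalg.inv(X)
        except np.linalg.LinAlgError as exc:
            raise DegenerateGeometryError("rank-deficient point set") from exc
        M = np.einsum("ij,jk,ik->i", Q, Xi, Q)
        j = int(np.argmax(M))
        mx = M[j]
        if mx <= (d + 1) * (1.0 + tol):
            break
        step = (mx - d - 1.0) / ((d + 1.0) * (mx - 1.0))
        if step <= 1e-12:
            break
        u *= 1.0 - step
        u[j] += step
    c = pts.T @ u
    S = pts.T @ (u[:, None] * pts) - np.outer(c, c)
    try:
        A = np.linalg.inv(S) / d
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError("degenerate (flat) point set") from exc
    return c, A


def fit_min_ellipse(mask: np.ndarray) -> EnclosingEllipse:
    """Minimum-area enclosing ellipse of a mask's foreground pixel centers.

    Computed on the convex hull of the foreground for speed; the result is
    inflated (by at most a fraction of a pixel) so every hull point is
    contained exactly. Masks with fewer than 5 boundary points, or collinear
    ones, raise :class:`DegenerateGeometryError`.
    """
    m = np.asarray(mask, dtype=bool)
    n_fg = int(m.sum())
    if n_fg < 5:
        raise DegenerateGeometryError(f"mask has only {n_fg} foreground pixels")
    # the hull depends only on boundary pixels; erode once to find them
    from scipy import ndimage as ndi

    boundary = m & ~ndi.binary_erosion(m)
    pts_rc = np.argwhere(boundary)
    pts_xy = pts_rc[:, ::-1].astype(np.float64)
    try:
        hull = ConvexHull(pts_xy)
    except QhullError as exc:
        raise DegenerateGeometryError("foreground is degenerate (collinear points)") from exc
    hull_pts = pts_xy[hull.vertices]
    if len(hull_pts) < 5:
        raise DegenerateGeometryError(f"mask has only {len(hull_pts)} boundary points")
    c, A = _mvee(hull_pts)
    # guarantee containment of all hull points: inflate by the worst violation
    p = hull_pts - c
    q = np.einsum("ij,jk,ik->i", p, A, p)
    qmax = float(q.max())
    if qmax > 1.0:
        A = A / qmax
    vals, vecs = np.linalg.eigh(A)
    if np.any(vals <= 0):
        raise DegenerateGeometryError("degenerate ellipse (non-positive axis)")
    semi = 1.0 / np.sqrt(vals)  # vals ascending -> semi descending
    major_vec = vecs[:, 0]
    if major_vec[0] < 0:
        major_vec = -major_vec
    angle = float(np.degrees(np.arctan2(major_vec[1], major_vec[0])))
    if angle <= -90.0:
        angle += 180.0
    return EnclosingEllipse(
        center=(float(c[0]), float(c[1])),
        semi_major=float(semi[0]),
        semi_minor=float(semi[1]),
        angle_deg=angle,
    )


def rect_from_ellipse(e: EnclosingEllipse) -> EnclosingRect:
    """Rectangle circumscribing the ellipse: same center and angle, sides 2a x 2b."""
    return EnclosingRect(
        center=e.center,
        width=2.0 * e.semi_major,
        height=2.0 * e.semi_minor,
        angle_deg=e.angle_deg,
    )


def _rotation_inverse_map(angle_deg: float, center: tuple[float, float]) -> AffineTransform:
    """Transform mapping output (x, y) to input coordinates for straightening."""
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, -s], [s, c]])
    ctr = np.asarray(center, dtype=np.float64)
    M = np.eye(3)
    M[:2, :2] = R
    M[:2, 2] = ctr - R @ ctr
    return AffineTransform(matrix=M)


def straighten(img: np.ndarray, r: EnclosingRect, order: int = 1):
    """Rotate the image about the rectangle center so the rectangle is axis-aligned.

    The direction of the rectangle's width axis is mapped to the +x axis;
    bilinear interpolation by default, out-of-canvas regions padded with 0.

    Returns ``(rotated_image, axis_aligned_rect)``.
    """
    tf = _rotation_inverse_map(r.angle_deg, r.center)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        out = warp(arr, tf, order=order, cval=0.0, preserve_range=True)
    elif arr.ndim == 3:
        out = np.stack(
            [warp(arr[..., k], tf, order=order, cval=0.0, preserve_range=True) for k in range(arr.shape[2])],
            axis=-1,
        )
    else:
        raise ValueError(f"expected a 2-D or 3-D image, got ndim={arr.ndim}")
    return out, EnclosingRect(center=r.center, width=r.width, height=r.height, angle_deg=0.0)


def crop_and_resize(
    img: np.ndarray,
    r: EnclosingRect,
    um_per_px: float,
    pupa_id: str = "",
    day_index: int = 1,
    color: np.ndarray | None = None,
) -> StandardPupaImage:
    """Crop an axis-aligned rectangle and resize to the standard frame.

    Crop bounds are half-open integers (floor of minima, ceil of maxima),
    clipped to the canvas. The per-axis calibration of the output is
    ``um_per_px * crop_extent / std_extent``.
    """
    if abs(r.angle_deg) > 1e-6:
        raise ValueError("rectangle must be axis-aligned (straighten first)")
    if r.width <= 0 or r.height <= 0:
        raise ValueError("degenerate rectangle (zero area)")
    arr = np.asarray(img, dtype=np.float64)
    H, W = arr.shape[:2]
    x0 = max(int(np.floor(r.center[0] - r.width / 2.0)), 0)
    x1 = min(int(np.ceil(r.center[0] + r.width / 2.0)), W)
    y0 = max(int(np.floor(r.center[1] - r.height / 2.0)), 0)
    y1 = min(int(np.ceil(r.center[1] + r.height / 2.0)), H)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("rectangle lies outside the canvas")
    std_width, std_height = STD_WIDTH, STD_HEIGHT
    crop = arr[y0:y1, x0:x1]
    if crop.shape[:2] == (std_height, std_width):
        out = crop.copy()
    else:
        out = resize(crop, (std_height, std_width), order=1, preserve_range=True, anti_aliasing=False)
    color_out = None
    if color is not None:
        ccrop = np.asarray(color, dtype=np.float64)[y0:y1, x0:x1]
        color_out = resize(ccrop, (std_height, std_width), order=1, preserve_range=True, anti_aliasing=False)
    cal_x = um_per_px * (x1 - x0) / float(std_width)
    cal_y = um_per_px * (y1 - y0) / float(std_height)
    return StandardPupaImage(
        pixels=out.astype(np.float32),
        um_per_px_std=(cal_x, cal_y),
        pupa_id=pupa_id,
        day_index=day_index,
        color=color_out,
    )
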