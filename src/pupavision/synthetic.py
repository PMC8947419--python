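"""Seeded generator of pupal day-series images with known ground truth.

Emulates the acquisition design of the study the pipeline targets: one pupa
per frame, one 3-channel wide-range TIFF per day for up to 11 days, with
eclosion on day ``n_days + 1`` for pupae that emerge. The rendered pupa is a
bright, saturated ellipse on a near-neutral background at a random rotation.
Two days before eclosion, short light setae (0.02-0.05 mm) appear on the tail
of both sexes, and 16-20 long dark pectinate setae (0.05-0.18 mm) appear on
males only. Unfledged pupae (died before emergence) never develop setae.

The body is rendered in a canonical tail-left pose and rotated by a per-pupa
angle well inside (-90, 90) deg, so pose normalization recovers the canonical
orientation without a flip and the setae band lands in grid cell 17 of the
standard frame (row 4, column 2), matching the discriminative cell of the
study. All randomness derives from the config seed; identical configs produce
bit-identical cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from pupavision.preprocess import RAW_MAX, RawPupaImage

# band of the tail setae in body-fraction coordinates: u along the major axis
# (-1 = tail tip), v along the minor axis (+1 = ventral/lower edge). The band
# maps into grid cell 17 (u in [-0.6, -0.2), v in [0.2, 0.6)) of the standard
# frame with margin for the stripes' own extent.
_LONG_U = (-0.55, -0.34)  # mid third tail segment
_SHORT_U = (-0.33, -0.23)  # third/fourth segment junction
_SETAE_ROW_V = (0.36, 0.44)  # per-pupa height of the comb row on the ventral side

_BG_RGB = np.array([0.52, 0.55, 0.58])  # low saturation (~0.10)
_BODY_RGB = np.array([0.80, 0.50, 0.20])  # high saturation (0.75)


def round_half_up_int(x: float) -> int:
    """Round half up to an integer (0.5 -> 1, 1.5 -> 2)."""
    return int(np.floor(x + 0.5))


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Lengths are physical (mm); ``um_per_px`` sets the raw-image scale
    (default 5 um/px, so a 4 mm pupa spans ~800 px). ``noise_sd`` is the
    standard deviation of additive Gaussian noise in raw gray levels (on the
    [0, 65520] scale).
    """

    n_pupae: int = 100
    male_fraction: float = 0.5
    unfledged_fraction: float = 0.1
    n_days: int = 11
    setae_onset_days_before_eclosion: int = 2
    long_setae_length_range_mm: tuple[float, float] = (0.05, 0.18)
    short_setae_length_range_mm: tuple[float, float] = (0.02, 0.05)
    setae_count_range: tuple[int, int] = (16, 20)
    um_per_px: float = 5.0
    image_width_px: int = 1000
    image_height_px: int = 800
    noise_sd: float = 600.0
    rotation_range_deg: tuple[float, float] = (-35.0, 35.0)
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_pupae < 0:
            raise ValueError("n_pupae must be >= 0")
        for name in ("male_fraction", "unfledged_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("long_setae_length_range_mm", "short_setae_length_range_mm"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval")
        lo, hi = self.setae_count_range
        if not (0 < lo <= hi):
            raise ValueError("setae_count_range must be a positive integer interval")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.rotation_range_deg
        if not (-90.0 < lo <= hi < 90.0):
            raise ValueError("rotation_range_deg must lie strictly inside (-90, 90)")
        return self


@dataclass
class GroundTruthRecord:
    """Per-pupa ground truth written to the cohort manifest.

    ``setae_visible_days`` lists the captured days on which the male-only
    long setae are rendered (always empty for females and unfledged pupae).
    """

    pupa_id: str
    true_sex: str  # male | female
    outcome: str  # male | female | unfledged
    eclosion_day: int | None
    setae_visible_days: frozenset = frozenset()
    um_per_px: float = 5.0

    def validate(self) -> "GroundTruthRecord":
        if self.true_sex not in ("male", "female"):
            raise ValueError(f"invalid true_sex {self.true_sex!r}")
        if self.outcome not in ("male", "female", "unfledged"):
            raise ValueError(f"invalid outcome {self.outcome!r}")
        if self.outcome == "unfledged":
            if self.eclosion_day is not None:
                raise ValueError("unfledged records must have no eclosion_day")
            if self.setae_visible_days:
                raise ValueError("unfledged records must have no setae days")
        else:
            if self.outcome != self.true_sex:
                raise ValueError("outcome of an emerged pupa must equal true_sex")
            if self.eclosion_day is None:
                raise ValueError("emerged records need an eclosion_day")
        if self.true_sex == "male" and self.eclosion_day is not None:
            window = {self.eclosion_day - 2, self.eclosion_day - 1}
            if not set(self.setae_visible_days) <= window:
                raise ValueError("male setae days must lie within the 2 days before eclosion")
        return self


@dataclass(frozen=True)
class StripeSpec:
    """Ground-truth geometry of one rendered seta (body-fraction coordinates)."""

    u: float
    v: float
    length_mm: float
    width_mm: float
    tilt_deg: float  # deviation from perpendicular-to-major-axis
    depth: float  # multiplicative darkening at the core, in (0, 1)
    kind: str  # "long" | "short"


@dataclass(frozen=True)
class BodyPlan:
    """Per-pupa rendered body geometry (raw-image pixels)."""

    center: tuple[float, float]
    semi_major_px: float
    semi_minor_px: float
    angle_deg: float
    day_jitter_deg: tuple


def _id_hash(pupa_id: str) -> int:
    return zlib.crc32(pupa_id.encode("utf8")) & 0x7FFFFFFF


def _pupa_rng(cfg: GeneratorConfig, pupa_id: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, _id_hash(pupa_id), *extra]))


def _setae_window(cfg: GeneratorConfig, record: GroundTruthRecord) -> set[int]:
    """Captured days in the 2-day pre-eclosion window (both-sex short setae)."""
    if record.eclosion_day is None:
        return set()
    k = cfg.setae_onset_days_before_eclosion
    return {d for d in range(record.eclosion_day - k, record.eclosion_day) if 1 <= d <= cfg.n_days}


def plan_pupa(cfg: GeneratorConfig, record: GroundTruthRecord):
    """Deterministic per-pupa body geometry and setae set.

    Returns ``(BodyPlan, list[StripeSpec])``. The same (config, record) pair
    always yields the same plan; the setae set is fixed across the days it is
    visible (the anatomy does not change day to day).
    """
    rng = _pupa_rng(cfg, record.pupa_id)
    px_per_mm = 1000.0 / cfg.um_per_px
    a = rng.uniform(1.80, 2.00) * px_per_mm
    b = rng.uniform(0.72, 0.82) * px_per_mm
    cx = cfg.image_width_px / 2.0 + rng.uniform(-15.0, 15.0)
    cy = cfg.image_height_px / 2.0 + rng.uniform(-15.0, 15.0)
    angle = rng.uniform(*cfg.rotation_range_deg)
    jitter = tuple(rng.uniform(-2.0, 2.0, size=cfg.n_days))
    plan = BodyPlan(
        center=(cx, cy),
        semi_major_px=a,
        semi_minor_px=b,
        angle_deg=angle,
        day_jitter_deg=jitter,
    )
    stripes: list[StripeSpec] = []
    if _setae_window(cfg, record):
        # setae form a comb: evenly spaced along a common row with small
        # jitter, near-parallel within one pupa (base tilt per pupa, small
        # per-seta jitter, total within +-20 deg of perpendicular to the
        # body axis)
        base_tilt = rng.uniform(-15.0, 15.0)
        row_v = rng.uniform(*_SETAE_ROW_V)
        n_short = int(rng.integers(6, 11))
        for u0, du in _comb_positions(rng, _SHORT_U, n_short):
            stripes.append(
                StripeSpec(
                    u=u0 + du,
                    v=row_v + rng.uniform(-0.005, 0.005),
                    length_mm=rng.uniform(*cfg.short_setae_length_range_mm),
                    width_mm=rng.uniform(0.006, 0.009),
                    tilt_deg=base_tilt + rng.uniform(-5.0, 5.0),
                    depth=rng.uniform(0.25, 0.35),
                    kind="short",
                )
            )
        if record.true_sex == "male" and record.outcome == "male":
            lo, hi = cfg.setae_count_range
            n_long = int(rng.integers(lo, hi + 1))
            for u0, du in _comb_positions(rng, _LONG_U, n_long):
                stripes.append(
                    StripeSpec(
                        u=u0 + du,
                        v=row_v + rng.uniform(-0.01, 0.01),
                        length_mm=rng.uniform(*cfg.long_setae_length_range_mm),
                        width_mm=rng.uniform(0.010, 0.015),
                        tilt_deg=base_tilt + rng.uniform(-5.0, 5.0),
                        depth=rng.uniform(0.50, 0.60),
                        kind="long",
                    )
                )
    return plan, stripes


def _comb_positions(rng: np.random.Generator, band: tuple[float, float], n: int):
    """Evenly spaced comb positions across a band with +-10% spacing jitter.

    The jitter bound keeps neighboring setae from overlapping, which is also
    what the comb anatomy dictates.
    """
    lo, hi = band
    centers = np.linspace(lo, hi, n)
    spacing = (hi - lo) / max(n - 1, 1)
    jitter = rng.uniform(-0.1 * spacing, 0.1 * spacing, size=n)
    return list(zip(centers, jitter))


def drawn_setae(cfg: GeneratorConfig, record: GroundTruthRecord) -> list[StripeSpec]:
    """Ground-truth setae set of one pupa (empty for pupae that never eclose)."""
    return plan_pupa(cfg, record)[1]


def _stamp_capsule(D: np.ndarray, p0, p1, width_px: float, depth: float):
    """Darken an anti-aliased capsule (segment with round caps) into D (max-combine)."""
    H, W = D.shape
    margin = width_px / 2.0 + 2.0
    x0 = max(int(np.floor(min(p0[0], p1[0]) - margin)), 0)
    x1 = min(int(np.ceil(max(p0[0], p1[0]) + margin)) + 1, W)
    y0 = max(int(np.floor(min(p0[1], p1[1]) - margin)), 0)
    y1 = min(int(np.ceil(max(p0[1], p1[1]) + margin)) + 1, H)
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        t = np.zeros_like(xx, dtype=np.float64)
    else:
        t = np.clip(((xx - p0[0]) * dx + (yy - p0[1]) * dy) / seg2, 0.0, 1.0)
    px = p0[0] + t * dx
    py = p0[1] + t * dy
    dist = np.hypot(xx - px, yy - py)
    cov = np.clip(width_px / 2.0 + 0.5 - dist, 0.0, 1.0)
    patch = D[y0:y1, x0:x1]
    np.maximum(patch, cov * depth, out=patch)


def render_day(cfg: GeneratorConfig, record: GroundTruthRecord, day_index: int):
    """Render one day's raw frame.

    Returns ``(image_float01, true_body_mask)`` where the image is (H, W, 3)
    in [0, 1] before range scaling and noise, and the mask is the exact
    rasterized body ellipse (elliptical radius <= 1).
    """
    plan, stripes = plan_pupa(cfg, record)
    H, W = cfg.image_height_px, cfg.image_width_px
    a, b = plan.semi_major_px, plan.semi_minor_px
    theta = np.deg2rad(plan.angle_deg + plan.day_jitter_deg[day_index - 1])
    ct, st = np.cos(theta), np.sin(theta)
    cx, cy = plan.center
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = _BG_RGB
    mask = np.zeros((H, W), dtype=bool)
    # the body affects only the rotated ellipse's bounding box (+AA margin)
    ex = abs(a * ct) + abs(b * st) + 3.0
    ey = abs(a * st) + abs(b * ct) + 3.0
    bx0, bx1 = max(int(cx - ex), 0), min(int(cx + ex) + 1, W)
    by0, by1 = max(int(cy - ey), 0), min(int(cy + ey) + 1, H)
    yy, xx = np.mgrid[by0:by1, bx0:bx1].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    R = np.hypot(u, v)
    mask[by0:by1, bx0:bx1] = R <= 1.0
    alpha = np.clip(0.5 + (1.0 - R) * b / 1.5, 0.0, 1.0)
    img[by0:by1, bx0:bx1] = (
        _BG_RGB[None, None, :] * (1.0 - alpha[..., None])
        + _BODY_RGB[None, None, :] * alpha[..., None]
    )

    window = _setae_window(cfg, record)
    if day_index in window:
        px_per_mm = 1000.0 / cfg.um_per_px
        e_major = np.array([ct, st])
        e_minor = np.array([-st, ct])
        center = np.array([cx, cy])
        D = np.zeros((H, W))
        for s in stripes:
            if s.kind == "long" and day_index not in record.setae_visible_days:
                continue
            p_c = center + s.u * a * e_major + s.v * b * e_minor
            psi = np.deg2rad(s.tilt_deg)
            dvec = np.sin(psi) * e_major + np.cos(psi) * e_minor
            L = s.length_mm * px_per_mm
            wpx = s.width_mm * px_per_mm
            half = max(L - wpx, 0.0) / 2.0  # caps included in the tip-to-tip length
            _stamp_capsule(D, p_c - half * dvec, p_c + half * dvec, wpx, s.depth)
        img = img * (1.0 - D)[..., None]
    return img, mask


def true_body_mask(cfg: GeneratorConfig, record: GroundTruthRecord, day_index: int) -> np.ndarray:
    """Exact rasterized body ellipse for one day (segmentation oracle)."""
    return render_day(cfg, record, day_index)[1]


def generate_pupa_series(cfg: GeneratorConfig, record: GroundTruthRecord) -> list[RawPupaImage]:
    """Generate the full day series of raw images for one pupa.

    Raises ``ValueError`` when the record is inconsistent with the config
    (calibration mismatch, eclosion outside the series, bad setae days).
    """
    cfg.validate()
    record.validate()
    if abs(record.um_per_px - cfg.um_per_px) > 1e-12:
        raise ValueError("record calibration does not match config")
    if record.eclosion_day is not None and record.eclosion_day > cfg.n_days + 1:
        raise ValueError("eclosion_day beyond the capture window")
    window = _setae_window(cfg, record)
    if not set(record.setae_visible_days) <= window:
        raise ValueError("setae_visible_days outside the pre-eclosion window of the series")
    series = []
    for day in range(1, cfg.n_days + 1):
        img, _ = render_day(cfg, record, day)
        rng = _pupa_rng(cfg, record.pupa_id, day)
        raw = (img * RAW_MAX).astype(np.float32)
        if cfg.noise_sd > 0:
            raw += rng.standard_normal(raw.shape, dtype=np.float32) * np.float32(cfg.noise_sd)
        pixels = np.clip(np.rint(raw), 0, RAW_MAX).astype(np.uint16)
        series.append(
            RawPupaImage(
                pixels=pixels,
                pupa_id=record.pupa_id,
                day_index=day,
                water_treated_day8=day >= 8,
            )
        )
    return series


def make_records(cfg: GeneratorConfig) -> list[GroundTruthRecord]:
    """Assign sexes and outcomes for a cohort.

    ``round_half_up(n_pupae * male_fraction)`` pupae are male; independently,
    ``round_half_up(n_pupae * unfledged_fraction)`` pupae are unfledged
    (chosen uniformly, irrespective of sex). Emerged pupae eclose on day
    ``n_days + 1``; male setae are visible on the last two captured days.
    """
    cfg.validate()
    n = cfg.n_pupae
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    n_male = round_half_up_int(n * cfg.male_fraction)
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    sexes = sexes[rng.permutation(n)] if n else sexes
    n_unf = round_half_up_int(n * cfg.unfledged_fraction)
    unfledged = np.zeros(n, dtype=bool)
    if n_unf:
        unfledged[rng.choice(n, size=n_unf, replace=False)] = True
    eclosion = cfg.n_days + 1
    records = []
    for i in range(n):
        sex = str(sexes[i])
        if unfledged[i]:
            rec = GroundTruthRecord(
                pupa_id=f"P{i:04d}",
                true_sex=sex,
                outcome="unfledged",
                eclosion_day=None,
                setae_visible_days=frozenset(),
                um_per_px=cfg.um_per_px,
            )
        else:
            days = frozenset(
                d for d in (eclosion - 2, eclosion - 1) if 1 <= d <= cfg.n_days
            ) if sex == "male" else frozenset()
            rec = GroundTruthRecord(
                pupa_id=f"P{i:04d}",
                true_sex=sex,
                outcome=sex,
                eclosion_day=eclosion,
                setae_visible_days=days,
                um_per_px=cfg.um_per_px,
            )
        records.append(rec.validate())
    return records


def generate_cohort(cfg: GeneratorConfig):
    """Generate the whole cohort.

    Returns ``(series_list, records)`` where ``series_list[i]`` is the day
    series of ``records[i]``. An empty config yields an empty cohort.
    """
    records = make_records(cfg)
    return [generate_pupa_series(cfg, rec) for rec in records], records
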