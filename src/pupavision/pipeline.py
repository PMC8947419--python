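"""Pipeline orchestration: preprocess -> segment -> pose -> grid -> setae -> evaluate.

Per-image failures (e.g. segmentation of a degenerate frame) are quarantined
and reported; they never abort a cohort run. All outputs are deterministic
for a fixed input set and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pupavision import io as pio
from pupavision.evaluate import EvaluationTable, build_table, summarize
from pupavision.geometry import (
    DegenerateGeometryError,
    crop_and_resize,
    fit_min_ellipse,
    rect_from_ellipse,
    straighten,
)
from pupavision.gridfeat import GridSpec, frame_features, make_grid, temporal_screen
from pupavision.preprocess import RawPupaImage, normalize_range, to_gray, to_hsv
from pupavision.segment import SegmentationError, segment_pupa
from pupavision.setae import ClassifierParams, PupaCall, SetaeCall, call_pupa, call_sex, detect_stripes

log = logging.getLogger("pupavision")


@dataclass
class PipelineConfig:
    """Everything a cohort run needs; YAML-loadable with CLI overrides."""

    input_dir: str = ""
    manifest_path: str = ""
    out_dir: str = "pupavision_out"
    in_max: int = 65520
    out_max: int = 255
    opening_radius: int = 5
    grid: GridSpec = field(default_factory=GridSpec)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    check_mirror_cell: bool = False
    debug_masks: bool = False
    debug_geometry: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("grid"), dict):
            raw["grid"] = GridSpec(**raw["grid"])
        if isinstance(raw.get("classifier"), dict):
            raw["classifier"] = ClassifierParams(**raw["classifier"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ImageResult:
    """Per-frame outputs: grid features and the tail-cell setae call.

    ``mask``/``ellipse``/``rect`` are populated only when debug output is
    requested.
    """

    features: pd.DataFrame
    call: SetaeCall
    um_per_px_std: tuple[float, float]
    residual_angle_deg: float
    mask: np.ndarray | None = None
    ellipse: object = None
    rect: object = None
    gray: np.ndarray | None = None


def process_image(raw: RawPupaImage, um_per_px: float, cfg: PipelineConfig) -> ImageResult:
    """Run one frame through preprocessing, segmentation, pose and detection."""
    raw.validate()
    norm = normalize_range(raw, in_max=cfg.in_max, out_max=cfg.out_max)
    _, s, _ = to_hsv(norm, compute_hue=False)
    mask = segment_pupa(s, cfg.opening_radius, raw.pupa_id, raw.day_index)
    ellipse = fit_min_ellipse(mask)
    rect = rect_from_ellipse(ellipse)
    gray = to_gray(norm)
    rotated, rect_aa = straighten(gray, rect)
    std = crop_and_resize(
        rotated,
        rect_aa,
        um_per_px,
        pupa_id=raw.pupa_id,
        day_index=raw.day_index,
    )
    feats = frame_features(std.pixels, cfg.grid, raw.pupa_id, raw.day_index)
    cells = {idx: view for idx, _, view in make_grid(std.pixels, cfg.grid)}
    tail_cells = [cfg.grid.tail_cell_index]
    if cfg.check_mirror_cell:
        mirror = cfg.grid.mirror_index(cfg.grid.tail_cell_index)
        if mirror != cfg.grid.tail_cell_index:
            tail_cells.append(mirror)
    stripes = []
    for idx in tail_cells:
        stripes.extend(
            detect_stripes(cells[idx], std.um_per_px_std, cfg.classifier, cell_index=idx)
        )
    call = call_sex(stripes, cfg.classifier, raw.pupa_id, raw.day_index)
    debug = cfg.debug_masks or cfg.debug_geometry
    return ImageResult(
        features=feats,
        call=call,
        um_per_px_std=std.um_per_px_std,
        residual_angle_deg=ellipse.angle_deg,
        mask=mask if debug else None,
        ellipse=ellipse if debug else None,
        rect=rect if debug else None,
        gray=gray if cfg.debug_geometry else None,
    )


def _write_debug_images(out_dir: Path, pupa_id: str, day_index: int, res: ImageResult, cfg: PipelineConfig):
    import imageio.v3 as iio
    from skimage.draw import polygon_perimeter

    if cfg.debug_masks and res.mask is not None:
        d = out_dir / "debug_masks"
        d.mkdir(parents=True, exist_ok=True)
        iio.imwrite(d / f"{pupa_id}_day{day_index}_mask.png", (res.mask * np.uint8(255)))
    if cfg.debug_geometry and res.ellipse is not None and res.gray is not None:
        d = out_dir / "debug_geometry"
        d.mkdir(parents=True, exist_ok=True)
        overlay = np.stack([np.clip(res.gray, 0, 255).astype(np.uint8)] * 3, axis=-1)
        h, w = overlay.shape[:2]
        bp = np.round(res.ellipse.boundary_points(720)).astype(int)
        ok = (bp[:, 0] >= 0) & (bp[:, 0] < w) & (bp[:, 1] >= 0) & (bp[:, 1] < h)
        overlay[bp[ok, 1], bp[ok, 0]] = (255, 0, 0)
        th = np.deg2rad(res.rect.angle_deg)
        c, s = np.cos(th), np.sin(th)
        hw, hh = res.rect.width / 2.0, res.rect.height / 2.0
        corners = np.array(
            [
                (res.rect.center[0] + sx * hw * c - sy * hh * s, res.rect.center[1] + sx * hw * s + sy * hh * c)
                for sx, sy in ((-1, -1), (1, -1), (1, 1), (-1, 1))
            ]
        )
        rr, cc = polygon_perimeter(corners[:, 1], corners[:, 0], shape=overlay.shape[:2], clip=True)
        overlay[rr, cc] = (0, 255, 0)
        iio.imwrite(d / f"{pupa_id}_day{day_index}_geometry.png", overlay)


def process_series(
    series: list[RawPupaImage],
    um_per_px: float,
    cfg: PipelineConfig | None = None,
):
    """In-memory pipeline for one pupa's day series.

    Returns ``(features_frame, daily_calls, pupa_call)``.
    """
    cfg = cfg or PipelineConfig()
    frames, calls = [], []
    for raw in series:
        res = process_image(raw, um_per_px, cfg)
        frames.append(res.features)
        calls.append(res.call)
    return pd.concat(frames, ignore_index=True), calls, call_pupa(calls)


def _calls_frames(daily_calls: list[SetaeCall], pupa_calls: list[PupaCall]):
    daily = pd.DataFrame(
        [
            {
                "pupa_id": c.pupa_id,
                "day_index": c.day_index,
                "long_stripe_count": c.long_stripe_count,
                "call": c.call,
            }
            for c in daily_calls
        ],
        columns=["pupa_id", "day_index", "long_stripe_count", "call"],
    )
    per_pupa = pd.DataFrame(
        [
            {
                "pupa_id": p.pupa_id,
                "positive": p.positive,
                "first_positive_day": "" if p.first_positive_day is None else p.first_positive_day,
            }
            for p in pupa_calls
        ],
        columns=["pupa_id", "positive", "first_positive_day"],
    )
    return daily, per_pupa


@dataclass
class PipelineResult:
    table: EvaluationTable | None
    screen: pd.DataFrame
    features: pd.DataFrame
    daily_calls: pd.DataFrame
    pupa_calls: pd.DataFrame
    failures: pd.DataFrame
    out_dir: Path


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full pipeline over a directory of day-series TIFFs.

    Writes features.csv, calls_daily.csv, calls_pupa.csv, screen.csv,
    failures.csv, report.csv and report.json under ``cfg.out_dir``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest = pio.read_manifest(cfg.manifest_path)
    series_paths = pio.discover_series(cfg.input_dir)
    if not series_paths:
        raise FileNotFoundError(f"no '<pupa_id>_day<d>.tif' images found in {cfg.input_dir}")
    cal = dict(zip(manifest["pupa_id"], manifest["um_per_px"]))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_feats, all_daily, all_pupa, failures = [], [], [], []
    for pid, paths in series_paths.items():
        if pid not in cal:
            failures.append({"pupa_id": pid, "day_index": "", "stage": "manifest", "error": "no manifest entry"})
            continue
        t0 = time.perf_counter()
        calls = []
        for path in paths:
            try:
                raw = pio.read_image(path)
                res = process_image(raw, float(cal[pid]), cfg)
            except (ValueError, SegmentationError, DegenerateGeometryError) as exc:
                day = _day_from_name(path.name)
                failures.append({"pupa_id": pid, "day_index": day, "stage": "image", "error": str(exc)})
                continue
            all_feats.append(res.features)
            calls.append(res.call)
            if cfg.debug_masks or cfg.debug_geometry:
                _write_debug_images(out_dir, pid, raw.day_index, res, cfg)
        if calls:
            all_daily.extend(calls)
            all_pupa.append(call_pupa(calls))
        else:
            failures.append({"pupa_id": pid, "day_index": "", "stage": "series", "error": "no usable frames"})
        log.info("pupa %s: %d frames in %.2fs", pid, len(paths), time.perf_counter() - t0)

    features = (
        pd.concat(all_feats, ignore_index=True)
        if all_feats
        else pd.DataFrame(columns=["pupa_id", "day_index", "cell_index", "mean_gray", "std_gray", "dark_fraction", "contrast"])
    )
    daily_df, pupa_df = _calls_frames(all_daily, all_pupa)
    fail_df = pd.DataFrame(failures, columns=["pupa_id", "day_index", "stage", "error"])

    try:
        screen = temporal_screen(features) if len(features) else pd.DataFrame(columns=["cell_index", "score"])
    except ValueError:
        screen = pd.DataFrame(columns=["cell_index", "score"])

    table = None
    if len(pupa_df):
        sub = manifest[manifest["pupa_id"].isin(pupa_df["pupa_id"])]
        table = build_table(pupa_df, sub)

    pio.atomic_write_text(out_dir / "features.csv", features.to_csv(index=False))
    pio.atomic_write_text(out_dir / "calls_daily.csv", daily_df.to_csv(index=False))
    pio.atomic_write_text(out_dir / "calls_pupa.csv", pupa_df.to_csv(index=False))
    pio.atomic_write_text(out_dir / "screen.csv", screen.to_csv(index=False))
    pio.atomic_write_text(out_dir / "failures.csv", fail_df.to_csv(index=False))
    if table is not None:
        text, frame = summarize(table)
        pio.atomic_write_text(out_dir / "report.csv", frame.to_csv(index=False))
        pio.atomic_write_text(
            out_dir / "report.json",
            json.dumps(dataclasses.asdict(table), indent=2, sort_keys=True) + "\n",
        )
    return PipelineResult(
        table=table,
        screen=screen,
        features=features,
        daily_calls=daily_df,
        pupa_calls=pupa_df,
        failures=fail_df,
        out_dir=out_dir,
    )


def _day_from_name(name: str):
    m = pio._IMAGE_RE.match(name)
    return int(m.group("day")) if m else ""
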