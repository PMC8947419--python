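"""File I/O: 16-bit TIFF day series, CSV manifests, atomic report writes.

Day-series images are named ``<pupa_id>_day<d>.tif``. The manifest is a CSV
with header ``pupa_id,true_sex,outcome,eclosion_day,um_per_px`` (empty
eclosion_day for unfledged pupae).
"""

from __future__ import annotations

import os
import re
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from pupavision.preprocess import RAW_MAX, RawPupaImage
from pupavision.synthetic import GeneratorConfig, GroundTruthRecord, generate_cohort

MANIFEST_COLUMNS = ["pupa_id", "true_sex", "outcome", "eclosion_day", "um_per_px"]
_IMAGE_RE = re.compile(r"^(?P<pid>.+)_day(?P<day>\d+)\.tif$")


def image_filename(pupa_id: str, day_index: int) -> str:
    return f"{pupa_id}_day{day_index}.tif"


def write_image(path: str | Path, img: RawPupaImage) -> None:
    tifffile.imwrite(str(path), np.asarray(img.pixels, dtype=np.uint16), photometric="rgb")


def read_image(path: str | Path) -> RawPupaImage:
    """Load and validate one raw frame; the filename supplies pupa id and day."""
    path = Path(path)
    m = _IMAGE_RE.match(path.name)
    if not m:
        raise ValueError(f"{path.name}: file name does not match '<pupa_id>_day<d>.tif'")
    px = tifffile.imread(str(path))
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"{path.name}: expected a 3-channel image, got shape {px.shape}")
    if int(px.max(initial=0)) > RAW_MAX:
        raise ValueError(f"{path.name}: pixel maximum {int(px.max())} exceeds {RAW_MAX}")
    day = int(m.group("day"))
    return RawPupaImage(
        pixels=px,
        pupa_id=m.group("pid"),
        day_index=day,
        water_treated_day8=day >= 8,
    )


def discover_series(input_dir: str | Path) -> dict[str, list[Path]]:
    """Map pupa_id -> day-sorted image paths found in a directory."""
    input_dir = Path(input_dir)
    series: dict[str, list[tuple[int, Path]]] = {}
    for p in sorted(input_dir.glob("*.tif")):
        m = _IMAGE_RE.match(p.name)
        if not m:
            continue
        series.setdefault(m.group("pid"), []).append((int(m.group("day")), p))
    return {pid: [p for _, p in sorted(v)] for pid, v in sorted(series.items())}


def manifest_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    rows = [
        {
            "pupa_id": r.pupa_id,
            "true_sex": r.true_sex,
            "outcome": r.outcome,
            "eclosion_day": "" if r.eclosion_day is None else r.eclosion_day,
            "um_per_px": r.um_per_px,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_manifest(path: str | Path, records: list[GroundTruthRecord]) -> None:
    atomic_write_text(path, manifest_frame(records).to_csv(index=False))


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"pupa_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    return df


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text via a temp file + rename so readers never see partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, str(path))
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_cohort(cfg: GeneratorConfig, out_dir: str | Path):
    """Generate a cohort and write its TIFFs and manifest under ``out_dir``.

    Returns ``(image_dir, manifest_path, records)``.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    series_list, records = generate_cohort(cfg)
    for series in series_list:
        for img in series:
            write_image(img_dir / image_filename(img.pupa_id, img.day_index), img)
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest_path, records)
    return img_dir, manifest_path, records
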