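"""5x5 grid meshing and per-cell texture features for temporal screening.

The standardized 2800x1300 frame is divided into 25 equal cells (row-major,
1-based, numbered from the top-left). For each cell and day, simple gray and
texture statistics are computed; the cell whose statistics change most over
the series relative to day 1 is the one carrying the discriminative signal.
On pupae oriented tail-left the setae band falls in cell 17 (row 4, col 2);
under a tail-right flip it falls in the mirrored cell 19.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_NAMES = ("mean_gray", "std_gray", "dark_fraction", "contrast")


@dataclass
class GridSpec:
    """Grid geometry and the index of the cell expected to carry the tail signal."""

    rows: int = 5
    cols: int = 5
    tail_cell_index: int = 17

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be positive")
        if not (1 <= self.tail_cell_index <= self.rows * self.cols):
            raise ValueError("tail_cell_index out of range")

    def cell_bounds(self, index: int, width: int, height: int):
        """Half-open pixel bounds (x0, x1, y0, y1) of a 1-based cell index."""
        if width % self.cols or height % self.rows:
            raise ValueError(
                f"image {width}x{height} not divisible into {self.rows}x{self.cols} equal cells"
            )
        if not (1 <= index <= self.rows * self.cols):
            raise ValueError("cell index out of range")
        cw, ch = width // self.cols, height // self.rows
        r, c = divmod(index - 1, self.cols)
        return c * cw, (c + 1) * cw, r * ch, (r + 1) * ch

    def mirror_index(self, index: int) -> int:
        """Cell index under a left-right flip of the image (same row, mirrored column)."""
        r, c = divmod(index - 1, self.cols)
        return r * self.cols + (self.cols - 1 - c) + 1


def make_grid(img: np.ndarray, spec: GridSpec = GridSpec()):
    """Split an image into rows x cols equal cells.

    Returns a list of ``(cell_index, (x0, x1, y0, y1), view)`` tuples in
    row-major order; the half-open bounds tile the image exactly.
    """
    arr = np.asarray(img)
    h, w = arr.shape[:2]
    cells = []
    for idx in range(1, spec.rows * spec.cols + 1):
        x0, x1, y0, y1 = spec.cell_bounds(idx, w, h)
        cells.append((idx, (x0, x1, y0, y1), arr[y0:y1, x0:x1]))
    return cells


def glcm_contrast(cell: np.ndarray, levels: int = 32) -> float:
    """Gray-level co-occurrence contrast, offset 1 px horizontal, 32 levels.

    Equals sum_ij P(i,j) (i-j)^2 over the normalized co-occurrence matrix,
    i.e. the mean squared quantized difference of horizontal neighbor pairs.
    """
    arr = np.asarray(cell, dtype=np.float64)
    q = np.clip(arr, 0, 255).astype(np.uint8) // (256 // levels)
    if q.shape[1] < 2:
        return 0.0
    d = q[:, 1:].astype(np.int64) - q[:, :-1].astype(np.int64)
    return float(np.mean(d.astype(np.float64) ** 2))


def cell_features(cell: np.ndarray) -> dict:
    """Gray/texture statistics of one cell.

    dark_fraction is the fraction of pixels strictly below the cell-adaptive
    threshold ``max(mean - 2*std, 0)``.
    """
    arr = np.asarray(cell, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty cell")
    mean = float(arr.mean())
    std = float(arr.std())
    thr = max(mean - 2.0 * std, 0.0)
    dark = float(np.mean(arr < thr))
    return {
        "mean_gray": mean,
        "std_gray": std,
        "dark_fraction": dark,
        "contrast": glcm_contrast(arr),
    }


def frame_features(img: np.ndarray, spec: GridSpec = GridSpec(), pupa_id: str = "", day_index: int = 1) -> pd.DataFrame:
    """Per-cell features of one standardized frame as a tidy DataFrame."""
    rows = []
    for idx, _, view in make_grid(img, spec):
        feats = cell_features(view)
        rows.append({"pupa_id": pupa_id, "day_index": day_index, "cell_index": idx, **feats})
    return pd.DataFrame(rows)


def temporal_screen(features: pd.DataFrame) -> pd.DataFrame:
    """Rank grid cells by their maximum day-over-day-1 change across the cohort.

    For each feature, the absolute per-pupa change of each cell on day d
    versus day 1 is averaged over the cohort, z-scored across all (cell, day)
    entries of that feature, and the per-cell score is the maximum over days
    and features. Returns a DataFrame (cell_index, score) sorted descending
    by score (ties broken by cell index).
    """
    df = features.copy()
    days = sorted(df["day_index"].unique())
    if len(days) < 2:
        raise ValueError("temporal screening needs features from at least 2 days")
    base_day = days[0]
    base = df[df["day_index"] == base_day][["pupa_id", "cell_index", *FEATURE_NAMES]]
    later = df[df["day_index"] != base_day]
    merged = later.merge(base, on=["pupa_id", "cell_index"], suffixes=("", "_base"))
    scores = None
    for feat in FEATURE_NAMES:
        merged["_delta"] = (merged[feat] - merged[f"{feat}_base"]).abs()
        m = merged.groupby(["cell_index", "day_index"])["_delta"].mean()
        sd = m.std(ddof=0)
        z = (m - m.mean()) / sd if sd > 0 else m * 0.0
        per_cell = z.groupby(level="cell_index").max()
        scores = per_cell if scores is None else np.maximum(scores, per_cell)
    out = scores.rename("score").reset_index().sort_values(
        ["score", "cell_index"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
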