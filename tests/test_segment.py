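from collections import deque

import numpy as np
import pytest

from pupavision.preprocess import normalize_range, to_hsv
from pupavision.segment import (
    SegmentationError,
    binarize,
    extract_pupa_region,
    fill_holes,
    open_morphological,
    otsu_threshold,
    segment_pupa,
)
from pupavision.synthetic import generate_pupa_series, true_body_mask


def otsu_brute_force(px: np.ndarray) -> int:
    """Exhaustive scan of all 256 split points maximizing between-class variance."""
    hist = np.bincount(px.ravel(), minlength=256).astype(float)
    n = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        v = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
        if v > best_v:  # strict: keeps the smallest tied t
            best_t, best_v = t, v
    return best_t


def fill_holes_bfs(mask: np.ndarray) -> np.ndarray:
    """Flood-fill the background from the border (4-connectivity); the rest is foreground."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    outside = np.zeros_like(m)
    dq = deque()
    for i in range(h):
        for j in (0, w - 1):
            if not m[i, j] and not outside[i, j]:
                outside[i, j] = True
                dq.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not m[i, j] and not outside[i, j]:
                outside[i, j] = True
                dq.append((i, j))
    while dq:
        i, j = dq.popleft()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < h and 0 <= b < w and not m[a, b] and not outside[a, b]:
                outside[a, b] = True
                dq.append((a, b))
    return ~outside


def opening_brute_force(mask: np.ndarray, radius: int) -> np.ndarray:
    """Sliding-window erosion (min) then dilation (max) with a disk element."""
    from skimage.morphology import disk

    fp = disk(radius).astype(bool)
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    r = radius
    offs = [(i - r, j - r) for i in range(2 * r + 1) for j in range(2 * r + 1) if fp[i, j]]

    def erode(x):
        out = np.zeros_like(x)
        for i in range(h):
            for j in range(w):
                out[i, j] = all(
                    0 <= i + di < h and 0 <= j + dj < w and x[i + di, j + dj] for di, dj in offs
                )
        return out

    def dilate(x):
        out = np.zeros_like(x)
        for i in range(h):
            for j in range(w):
                out[i, j] = any(
                    0 <= i + di < h and 0 <= j + dj < w and x[i + di, j + dj] for di, dj in offs
                )
        return out

    return dilate(erode(m))


class TestOtsu:
    def test_two_level_image(self):
        px = np.array([[10] * 50 + [200] * 50], dtype=np.uint8)
        t = otsu_threshold(px)
        assert 10 <= t <= 199
        assert t == otsu_brute_force(px)

    def test_three_level_image(self):
        px = np.array([[0] * 30 + [100] * 50 + [255] * 20], dtype=np.uint8)
        assert otsu_threshold(px) == otsu_brute_force(px)

    def test_random_images_match_exhaustive_scan(self, rng):
        for _ in range(30):
            px = rng.integers(0, 256, size=(12, 17)).astype(np.uint8)
            assert otsu_threshold(px) == otsu_brute_force(px)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full((5, 5), 42, dtype=np.uint8))


class TestBinarize:
    def test_empty_and_full(self):
        px = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert not binarize(px, 255).any()
        assert binarize(px, -1).all()

    def test_covers_rendered_body_within_two_percent(self, small_cfg, small_records):
        rec = small_records[0]
        raw = generate_pupa_series(small_cfg, rec)[0]
        _, s, _ = to_hsv(normalize_range(raw))
        mask = binarize(s, otsu_threshold(s))
        true = true_body_mask(small_cfg, rec, 1)
        sym_diff = np.logical_xor(mask, true).sum()
        assert sym_diff / true.sum() < 0.02


class TestFillHoles:
    def test_ring_becomes_disk(self):
        yy, xx = np.mgrid[0:21, 0:21]
        r2 = (yy - 10) ** 2 + (xx - 10) ** 2
        ring = (r2 <= 81) & (r2 >= 36)
        filled = fill_holes(ring)
        assert np.array_equal(filled, r2 <= 81)

    def test_border_connected_cavity_unchanged(self):
        m = np.ones((7, 7), dtype=bool)
        m[3, 3] = False
        m[3, 4:] = False  # channel to the border
        assert np.array_equal(fill_holes(m), m)

    def test_random_masks_match_flood_fill_oracle(self, rng):
        for _ in range(10):
            m = rng.random((15, 18)) < 0.45
            assert np.array_equal(fill_holes(m), fill_holes_bfs(m))


class TestOpening:
    def test_isolated_pixel_removed(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert not open_morphological(m, 1).any()

    def test_anti_extensive_on_rectangle(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:25, 5:25] = True
        opened = open_morphological(m, 3)
        assert opened.sum() <= m.sum()
        assert not (opened & ~m).any()

    def test_matches_sliding_window_oracle(self, rng):
        m = rng.random((16, 16)) < 0.6
        assert np.array_equal(open_morphological(m, 2), opening_brute_force(m, 2))

    def test_idempotent(self, rng):
        m = rng.random((40, 40)) < 0.55
        once = open_morphological(m, 2)
        assert np.array_equal(open_morphological(once, 2), once)


class TestExtractRegion:
    def test_keeps_largest_component(self):
        m = np.zeros((20, 40), dtype=bool)
        m[2:12, 2:12] = True  # area 100
        m[15:16, 30:35] = True  # area 5
        out = extract_pupa_region(m)
        assert out[5, 5] and not out[15, 32]
        assert out.sum() == 100

    def test_empty_mask_raises_with_context(self):
        with pytest.raises(SegmentationError, match="P0042"):
            extract_pupa_region(np.zeros((5, 5), dtype=bool), pupa_id="P0042", day_index=3)


class TestFullChain:
    def test_dice_overlap_against_generator_raster(self, small_cfg, small_records):
        rec = small_records[0]
        raw = generate_pupa_series(small_cfg, rec)[0]
        _, s, _ = to_hsv(normalize_range(raw))
        mask = segment_pupa(s)
        true = true_body_mask(small_cfg, rec, 1)
        dice = 2.0 * np.logical_and(mask, true).sum() / (mask.sum() + true.sum())
        assert dice >= 0.95
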