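"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use brute-force pixel arithmetic (loops,
rasterized masks) rather than the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from irf_cellfinder.core_io import BBox, Image2D


def rasterize_box(b: BBox, shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[b.row0 : b.row1, b.col0 : b.col1] = True
    return m


def dice_by_pixel_counting(a: BBox, b: BBox, shape: tuple[int, int] = (64, 64)) -> float:
    """Dice from rasterized masks: 2|A&B| / (|A|+|B|)."""
    ma, mb = rasterize_box(a, shape), rasterize_box(b, shape)
    return 2.0 * np.sum(ma & mb) / (np.sum(ma) + np.sum(mb))


def brute_force_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a ball structuring element, by direct loops.

    Border convention: only in-image pixels participate in the min/max
    windows (equivalent to padding with +/- infinity).
    """
    n, m = img.shape
    offs = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            d2 = dr * dr + dc * dc
            if d2 <= radius * radius:
                offs.append((dr, dc, np.sqrt(radius * radius - d2)))
    ero = np.full_like(img, np.inf, dtype=float)
    for r in range(n):
        for c in range(m):
            best = np.inf
            for dr, dc, h in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n and 0 <= cc < m:
                    best = min(best, img[rr, cc] - h)
            ero[r, c] = best
    out = np.full_like(img, -np.inf, dtype=float)
    for r in range(n):
        for c in range(m):
            best = -np.inf
            for dr, dc, h in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n and 0 <= cc < m:
                    best = max(best, ero[rr, cc] + h)
            out[r, c] = best
    return out


def random_boxes(rng: np.random.Generator, n: int, shape: tuple[int, int] = (64, 64)) -> list[BBox]:
    boxes = []
    for _ in range(n):
        r0 = int(rng.integers(0, shape[0] - 2))
        c0 = int(rng.integers(0, shape[1] - 2))
        r1 = int(rng.integers(r0 + 1, shape[0]))
        c1 = int(rng.integers(c0 + 1, shape[1]))
        boxes.append(BBox(r0, c0, r1, c1))
    return boxes


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_image() -> Image2D:
    return Image2D(np.full((64, 64), 50.0))
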