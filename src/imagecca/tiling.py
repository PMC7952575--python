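"""Slide tiling, tissue-tile selection and window sampling.

A slide is divided into a grid of square tiles (default 1000x1000 px).  A
tile is kept only if its mean gray value and those of its four edge
neighbours are all darker than a threshold (default 180/255); the means
are computed on a x16 box-filtered downsample of the slide, as tile
statistics on full-resolution slides are needlessly expensive.  Training
windows (default 128x128) are then cropped uniformly at random from the
selected tiles, optionally rotated by a multiple of 90 degrees.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SlideTiles",
    "WindowBatch",
    "to_grayscale",
    "select_tiles",
    "sample_windows",
]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SlideTiles:
    """Tissue-dense tiles of one slide, in full-resolution coordinates."""

    slide_id: str
    tile_size: int
    coords: list          # [(row_px, col_px), ...] upper-left corners
    downsample_factor: int = 16
    tile_means: pd.DataFrame | None = None   # all tiles' mean gray values

    def __len__(self):
        return len(self.coords)


@dataclass
class WindowBatch:
    """m RGB windows in [0, 1] sampled from one sample's selected tiles."""

    sample_id: str
    windows: np.ndarray   # (m, w, w, 3) float32
    index: pd.DataFrame   # tile_row, tile_col, offset_row, offset_col, rotation
    seed: int = 0

    @property
    def m(self) -> int:
        return self.windows.shape[0]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luminance 0.299 R + 0.587 G + 0.114 B, preserving [0, 255]."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return img.astype(float) @ _LUMA


def _box_downsample(gray: np.ndarray, factor: int) -> np.ndarray:
    """Box-filter downsample by an integer factor (edge remainder cropped)."""
    h, w = gray.shape
    h2, w2 = h // factor, w // factor
    g = gray[:h2 * factor, :w2 * factor]
    return g.reshape(h2, factor, w2, factor).mean(axis=(1, 3))


def select_tiles(slide: np.ndarray, tile_size: int = 1000,
                 threshold: float = 180.0, downsample_factor: int = 16,
                 slide_id: str = "slide") -> SlideTiles:
    """Select tissue-dense tiles by the darkness rule.

    A tile is selected iff its own mean gray value and the mean gray values
    of the tiles above, below, left and right of it are all strictly below
    ``threshold``.  Means are taken on the x``downsample_factor`` box-filtered
    slide; returned coordinates are upper-left corners in full resolution.
    Border tiles have fewer than four neighbours and are never selected.
    """
    slide = np.asarray(slide)
    gray = to_grayscale(slide) if slide.ndim == 3 else slide.astype(float)
    small = _box_downsample(gray, downsample_factor)
    n_rows = gray.shape[0] // tile_size
    n_cols = gray.shape[1] // tile_size
    if n_rows < 3 or n_cols < 3:
        warnings.warn(
            f"slide {slide_id}: {n_rows}x{n_cols} tiles is too small for the "
            "4-neighbour rule; no tiles selected")
        return SlideTiles(slide_id, tile_size, [], downsample_factor)

    # per-tile mean gray from the downsampled image (fractional tile edges
    # fall on the nearest downsampled pixel boundary)
    means = np.empty((n_rows, n_cols))
    step = tile_size / downsample_factor
    for r in range(n_rows):
        r0, r1 = int(np.floor(r * step)), int(np.floor((r + 1) * step))
        for c in range(n_cols):
            c0, c1 = int(np.floor(c * step)), int(np.floor((c + 1) * step))
            means[r, c] = small[r0:r1, c0:c1].mean()

    dark = means < threshold
    selected = dark.copy()
    selected[0, :] = selected[-1, :] = False
    selected[:, 0] = selected[:, -1] = False
    interior = selected[1:-1, 1:-1]
    interior &= dark[:-2, 1:-1] & dark[2:, 1:-1] & dark[1:-1, :-2] & dark[1:-1, 2:]
    coords = [(int(r * tile_size), int(c * tile_size))
              for r, c in zip(*np.nonzero(selected))]
    mean_df = pd.DataFrame(means)
    return SlideTiles(slide_id, tile_size, coords, downsample_factor, mean_df)


def sample_windows(slide: np.ndarray, tiles: SlideTiles, m: int = 100,
                   window: int = 128, augment: bool = True,
                   seed: int = 0) -> WindowBatch:
    """Sample m windows uniformly over (selected tile, valid offset).

    Each window lies fully inside one selected tile; with ``augment`` it is
    rotated by an independently drawn multiple of 90 degrees.  Pixel values
    are scaled to [0, 1] float32.  Deterministic under ``seed``.
    """
    if len(tiles) == 0:
        raise ValueError(f"slide {tiles.slide_id}: no selected tiles to sample from")
    if m < 1:
        raise ValueError("m must be >= 1")
    if tiles.tile_size < window:
        raise ValueError(f"tile size {tiles.tile_size} smaller than window {window}")
    slide = np.asarray(slide)
    rng = np.random.default_rng(seed)
    max_off = tiles.tile_size - window
    out = np.empty((m, window, window, 3), dtype=np.float32)
    rows = []
    tile_idx = rng.integers(0, len(tiles), size=m)
    off_r = rng.integers(0, max_off + 1, size=m)
    off_c = rng.integers(0, max_off + 1, size=m)
    rots = rng.integers(0, 4, size=m) if augment else np.zeros(m, dtype=int)
    for i in range(m):
        tr, tc = tiles.coords[tile_idx[i]]
        r0, c0 = tr + off_r[i], tc + off_c[i]
        win = slide[r0:r0 + window, c0:c0 + window, :]
        if rots[i]:
            win = np.rot90(win, k=int(rots[i]))
        out[i] = win.astype(np.float32) / 255.0
        rows.append({
            "tile_row": tr, "tile_col": tc,
            "offset_row": int(off_r[i]), "offset_col": int(off_c[i]),
            "rotation": int(rots[i]) * 90,
        })
    return WindowBatch(sample_id=tiles.slide_id, windows=out,
                       index=pd.DataFrame(rows), seed=seed)
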