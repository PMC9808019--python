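"""Sliding-window tile extraction with Otsu background rejection.

Slides are divided into 256 x 256 patches on a stride-128 grid (row-major,
fully contained tiles only). Foreground/background separation uses a single
global Otsu threshold per slide, computed on an 8-bit luminance histogram of
a thumbnail downsampled by the stride; a tile is kept when at most 75% of its
pixels are brighter than that threshold (H&E background is the bright class).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .manifest import RegionReader

TILE_SIZE = 256
TILE_STRIDE = 128
MAX_BACKGROUND_FRACTION = 0.75

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class OtsuResult:
    """Grey-level threshold maximising between-class variance."""

    threshold: int
    between_class_variance: float


@dataclass(frozen=True)
class TileCoord:
    """One tile of the sliding-window grid; ``kept`` set after filtering."""

    x: int
    y: int
    size: int = TILE_SIZE
    kept: bool = True
    background_fraction: float = 0.0


@dataclass
class TileGrid:
    """Row-major enumeration of fully contained tiles over one slide."""

    slide_id: str
    width: int
    height: int
    size: int = TILE_SIZE
    stride: int = TILE_STRIDE
    tiles: list[TileCoord] = field(default_factory=list)

    @property
    def kept_tiles(self) -> list[TileCoord]:
        return [t for t in self.tiles if t.kept]


def luminance(rgb: np.ndarray) -> np.ndarray:
    """8-bit luminance (0.299 R + 0.587 G + 0.114 B, rounded)."""
    grey = np.tensordot(rgb[..., :3].astype(np.float64), _LUMA_WEIGHTS, axes=1)
    return np.clip(np.rint(grey), 0, 255).astype(np.uint8)


def compute_otsu(histogram: np.ndarray) -> OtsuResult:
    """Otsu's threshold from a 256-bin grey-level histogram.

    Maximises the between-class variance w0*w1*(mu0 - mu1)^2 over every
    candidate split (class 0 = levels <= t); ties resolve to the lowest
    level so the result is deterministic.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist) / total  # P(level <= t)
    m0 = np.cumsum(hist * levels) / total  # first moment up to t
    mu_total = m0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=0.0)
    t = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximiser
    return OtsuResult(threshold=t, between_class_variance=float(sigma_b[t]))


def slide_otsu_threshold(
    reader: RegionReader, downsample: int = TILE_STRIDE
) -> OtsuResult:
    """Global per-slide Otsu threshold from a block-mean thumbnail.

    The thumbnail is the slide block-averaged by ``downsample`` (default: the
    tile stride), converted to luminance; one threshold serves every tile of
    the slide, which keeps near-empty tiles from producing erratic per-patch
    thresholds.
    """
    w, h = reader.dims
    image = reader.read_region(0, 0, w, h).astype(np.float64)
    ds = max(1, int(downsample))
    hc, wc = (h // ds) * ds, (w // ds) * ds
    if hc == 0 or wc == 0:  # slide smaller than one block: use raw pixels
        thumb = image
    else:
        thumb = (
            image[:hc, :wc]
            .reshape(hc // ds, ds, wc // ds, ds, 3)
            .mean(axis=(1, 3))
        )
    grey = luminance(thumb)
    hist = np.bincount(grey.ravel(), minlength=256).astype(np.float64)
    return compute_otsu(hist)


def build_tile_grid(
    width: int,
    height: int,
    size: int = TILE_SIZE,
    stride: int = TILE_STRIDE,
    slide_id: str = "",
) -> TileGrid:
    """Row-major grid of fully contained tiles; edge remainders are dropped."""
    if size <= 0 or stride <= 0:
        raise ValueError("size and stride must be positive")
    nx = (width - size) // stride + 1 if width >= size else 0
    ny = (height - size) // stride + 1 if height >= size else 0
    tiles = [
        TileCoord(x=ix * stride, y=iy * stride, size=size)
        for iy in range(ny)
        for ix in range(nx)
    ]
    return TileGrid(
        slide_id=slide_id, width=width, height=height, size=size,
        stride=stride, tiles=tiles,
    )


def background_fraction(patch: np.ndarray, otsu_threshold: int) -> float:
    """Fraction of patch pixels strictly brighter than the Otsu threshold."""
    grey = luminance(patch)
    return float(np.mean(grey > otsu_threshold))


def filter_tiles(
    grid: TileGrid,
    reader: RegionReader,
    otsu_threshold: int,
    max_background: float = MAX_BACKGROUND_FRACTION,
) -> TileGrid:
    """Annotate each tile with its background fraction and keep/discard flag.

    A tile is kept iff its background fraction is <= ``max_background``
    (tiles with *more than* 75% background are discarded). Order preserved.
    """
    w, h = reader.dims
    if w != grid.width or h != grid.height:
        raise ValueError("grid was built for different slide dimensions")
    tiles = []
    for t in grid.tiles:
        patch = reader.read_region(t.x, t.y, t.size, t.size)
        frac = background_fraction(patch, otsu_threshold)
        tiles.append(replace(t, background_fraction=frac, kept=frac <= max_background))
    return TileGrid(
        slide_id=grid.slide_id, width=grid.width, height=grid.height,
        size=grid.size, stride=grid.stride, tiles=tiles,
    )


def tile_slide(
    reader: RegionReader,
    slide_id: str = "",
    size: int = TILE_SIZE,
    stride: int = TILE_STRIDE,
    max_background: float = MAX_BACKGROUND_FRACTION,
) -> TileGrid:
    """Grid + Otsu + filtering for one slide in a single call."""
    w, h = reader.dims
    grid = build_tile_grid(w, h, size=size, stride=stride, slide_id=slide_id)
    otsu = slide_otsu_threshold(reader, downsample=stride)
    return filter_tiles(grid, reader, otsu.threshold, max_background=max_background)


def grid_to_frame(grid: TileGrid):
    """Tile-index table (slide_id, x, y, background_fraction, kept)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "slide_id": grid.slide_id,
            "x": [t.x for t in grid.tiles],
            "y": [t.y for t in grid.tiles],
            "background_fraction": [t.background_fraction for t in grid.tiles],
            "kept": [t.kept for t in grid.tiles],
        }
    )
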