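"""Patch-prediction heatmaps for localisation review.

Per-tile predictions are composited onto a downsampled raster of the slide:
where overlapping kept tiles disagree, the maximum prediction wins, and
regions covered by no kept tile (discarded background) carry a sentinel and
render black, so "confidently normal" (value 0) and "no tissue" remain
visually distinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .tiling import TileGrid


@dataclass
class HeatmapRaster:
    """Downsampled prediction raster plus its coverage mask."""

    values: np.ndarray  # float in [0, 1]; undefined where not covered
    covered: np.ndarray  # bool; False = discarded/background (sentinel)
    downsample: int


def render_heatmap(grid: TileGrid, predictions: np.ndarray,
                   class_index: int = 1, downsample: int = 32) -> HeatmapRaster:
    """Max-composite kept-tile predictions onto a downsampled raster.

    ``predictions`` has one (normal, coeliac) row per *kept* tile, in grid
    order; ``class_index`` selects the head (1 = coeliac). The raster has
    shape ``ceil(slide_dims / downsample)``; each raster pixel covered by
    several overlapping tiles shows their maximum prediction.
    """
    preds = np.asarray(predictions, dtype=np.float64)
    kept = grid.kept_tiles
    if preds.ndim == 2:
        preds = preds[:, class_index]
    if preds.shape[0] != len(kept):
        raise ValueError("predictions are not aligned with the kept tiles")
    out_h = -(-grid.height // downsample)
    out_w = -(-grid.width // downsample)
    values = np.zeros((out_h, out_w))
    covered = np.zeros((out_h, out_w), dtype=bool)
    if not kept:
        warnings.warn("slide has no kept tiles; heatmap is all background")
        return HeatmapRaster(values=values, covered=covered, downsample=downsample)
    for tile, p in zip(kept, preds):
        x0 = tile.x // downsample
        y0 = tile.y // downsample
        x1 = -(-(tile.x + tile.size) // downsample)
        y1 = -(-(tile.y + tile.size) // downsample)
        region = values[y0:y1, x0:x1]
        np.maximum(region, p, out=region)
        covered[y0:y1, x0:x1] = True
    return HeatmapRaster(values=values, covered=covered, downsample=downsample)


def compose_overlay(heatmap: HeatmapRaster, thumbnail: np.ndarray,
                    colormap: str = "viridis", opacity: float = 0.6) -> np.ndarray:
    """Alpha-blend the heatmap over an RGB thumbnail; sentinel pixels black.

    ``thumbnail`` must match the raster's shape. Covered pixels become
    ``(1 - opacity) * thumbnail + opacity * colormap(value)``; pixels with
    no kept-tile coverage are rendered solid black.
    """
    thumb = np.asarray(thumbnail)
    if thumb.shape[:2] != heatmap.values.shape:
        raise ValueError("thumbnail dimensions do not match the heatmap")
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must be in [0, 1]")
    cmap = colormaps[colormap]
    colours = cmap(np.clip(heatmap.values, 0.0, 1.0))[..., :3] * 255.0
    base = thumb[..., :3].astype(np.float64)
    blended = (1.0 - opacity) * base + opacity * colours
    out = np.where(heatmap.covered[..., None], blended, 0.0)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
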