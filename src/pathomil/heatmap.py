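"""Attention heatmaps: per-tile normalized attention rendered as an RGB
overlay aligned to the slide.

Softmax attention weights shrink as 1/K with bag size, so tiles are colored
by their rank percentile within the bag (average rank for ties, scaled by
1/K) rather than by the raw weight — the visual dynamic range is then
independent of how many tiles a slide has. Warm colors mark tiles the model
leaned on; cool colors mark low-influence tissue.

The colormap is a fixed tabulated blue-white-red ramp with integer RGB
anchors, so rendered colors are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .types import AttentionProfile
from .wsi import PatchGrid

__all__ = ["HeatmapRaster", "BWR_ANCHORS", "colormap_rgb", "normalize_attention", "render_heatmap"]

# Anchor table (position, RGB) of the diverging blue-white-red ramp.
BWR_ANCHORS: tuple[tuple[float, tuple[int, int, int]], ...] = (
    (0.0, (0, 0, 255)),
    (0.5, (255, 255, 255)),
    (1.0, (255, 0, 0)),
)


def colormap_rgb(scores: np.ndarray) -> np.ndarray:
    """Map scores in [0, 1] to uint8 RGB via linear interpolation of the anchors."""
    scores = np.clip(np.asarray(scores, dtype=float), 0.0, 1.0)
    positions = np.array([p for p, _ in BWR_ANCHORS])
    channels = np.array([c for _, c in BWR_ANCHORS], dtype=float)
    rgb = np.stack(
        [np.interp(scores, positions, channels[:, ch]) for ch in range(3)], axis=-1
    )
    return np.round(rgb).astype(np.uint8)


def normalize_attention(profile: AttentionProfile) -> np.ndarray:
    """Rank-percentile scores in (0, 1]: average rank of the softmax weight / K."""
    weights = profile.weights
    return rankdata(weights, method="average") / weights.size


@dataclass
class HeatmapRaster:
    """RGB overlay at a stated downsample of the slide."""

    image: np.ndarray  # (H, W, 3) uint8
    downsample: int
    colormap_id: str
    alpha: float
    scores: np.ndarray  # per-tile scalar field used to color the raster


def render_heatmap(
    scores: np.ndarray,
    grid: PatchGrid,
    slide_dims: tuple[int, int],
    downsample: int = 16,
    alpha: float = 1.0,
    base_image: np.ndarray | None = None,
) -> HeatmapRaster:
    """Fill each grid tile with its colormapped score.

    ``slide_dims`` is ``(width, height)``. With a ``base_image`` (the slide
    downsampled by the same factor) tile colors are alpha-blended over it
    and the background keeps the slide's pixels; otherwise the background is
    white and tiles are filled with the pure colormap color scaled by alpha
    against white. Tile order does not affect the result as tiles never
    overlap.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size != len(grid):
        raise ValueError(f"{scores.size} scores for {len(grid)} tiles")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    width, height = slide_dims
    out_h = int(np.ceil(height / downsample))
    out_w = int(np.ceil(width / downsample))
    if base_image is not None:
        base = np.asarray(base_image, dtype=float)
        if base.shape[:2] != (out_h, out_w):
            raise ValueError(
                f"base image shape {base.shape[:2]} does not match downsampled slide ({out_h}, {out_w})"
            )
    else:
        base = np.full((out_h, out_w, 3), 255.0)
    canvas = base.copy()

    colors = colormap_rgb(scores).astype(float)
    ts = grid.tile_size
    for (x, y), color in zip(grid.tiles, colors):
        x0, y0 = x // downsample, y // downsample
        x1 = min(int(np.ceil((x + ts) / downsample)), out_w)
        y1 = min(int(np.ceil((y + ts) / downsample)), out_h)
        canvas[y0:y1, x0:x1] = alpha * color + (1.0 - alpha) * canvas[y0:y1, x0:x1]

    return HeatmapRaster(
        image=np.round(canvas).astype(np.uint8),
        downsample=downsample,
        colormap_id="blue-white-red",
        alpha=alpha,
        scores=scores,
    )
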