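"""Slide preprocessing: tissue segmentation, non-overlapping grid patching at
the 20x-equivalent level, and patch feature extraction via a pluggable encoder.

Segmentation follows the common weakly-supervised-pathology recipe: work at a
fixed downsample, threshold the HSV saturation channel (Otsu, falling back to
an absolute cut on near-constant images), then morphological closing and
small-object removal. Glass background is near-white and low-saturation;
stained tissue is not.

Patching is a pure 256 px grid — tile corners are multiples of the tile
size, tiles never overlap, and a tile is kept when its tissue coverage meets
``min_tissue_fraction``.

The patch encoder is a contract (``PatchEncoder``): anything mapping one
RGB tile to a fixed-length vector. Production pipelines plug in a
pre-trained CNN; the bundled encoders are small deterministic ones suited to
flat test slides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce
from skimage.morphology import closing, disk, remove_small_objects

from .types import FeatureBag

__all__ = [
    "TissueMask",
    "PatchGrid",
    "PatchEncoder",
    "MeanRGBEncoder",
    "ChannelStatsEncoder",
    "segment_tissue",
    "grid_patches",
    "extract_features",
    "read_slide",
]

TILE_SIZE = 256


@dataclass
class TissueMask:
    """Binary tissue raster at a stated downsample of the slide."""

    mask: np.ndarray  # bool, (H/ds, W/ds)
    downsample: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.downsample <= 0:
            raise ValueError("downsample must be positive")

    @property
    def tissue_area_px(self) -> float:
        """Tissue area in slide-level pixels."""
        return float(self.mask.sum()) * self.downsample**2


@dataclass
class PatchGrid:
    """Grid-aligned tile corners retained for one slide.

    Corners are 0-based (x = column, y = row), multiples of ``tile_size``,
    half-open ``[x, x+tile) x [y, y+tile)``, sorted row-major.
    """

    slide_id: str
    tiles: np.ndarray  # (K, 2) int corners
    tile_size: int = TILE_SIZE
    level_magnification: str = "20x-equivalent"

    def __post_init__(self) -> None:
        self.tiles = np.asarray(self.tiles, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.tiles)


class PatchEncoder(Protocol):
    """Maps one (tile, tile, 3) RGB array to a fixed-length float vector."""

    name: str
    dim: int

    def __call__(self, tile: np.ndarray) -> np.ndarray: ...


class MeanRGBEncoder:
    """Toy encoder: per-channel mean scaled to [0, 1]. Deterministic, d=3."""

    name = "mean-rgb"
    dim = 3

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        return np.asarray(tile, dtype=float).reshape(-1, 3).mean(axis=0) / 255.0


class ChannelStatsEncoder:
    """Per-channel mean and standard deviation plus mean saturation/value, d=8."""

    name = "channel-stats"
    dim = 8

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        x = np.asarray(tile, dtype=float) / 255.0
        hsv = rgb2hsv(x)
        flat = x.reshape(-1, 3)
        return np.concatenate(
            [flat.mean(axis=0), flat.std(axis=0), [hsv[..., 1].mean(), hsv[..., 2].mean()]]
        )


ENCODERS: dict[str, Callable[[], PatchEncoder]] = {
    MeanRGBEncoder.name: MeanRGBEncoder,
    ChannelStatsEncoder.name: ChannelStatsEncoder,
}


def read_slide(path: str) -> np.ndarray:
    """Read a flat RGB slide image (TIFF or PNG) as a (H, W, 3) uint8 array.

    Test and desk-scale slides are flat images declared to be at 20x; a
    pyramidal reader can be substituted upstream by passing arrays directly
    to :func:`segment_tissue` / :func:`extract_features`.
    """
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[2] >= 3:
            return np.ascontiguousarray(arr[..., :3])
        raise ValueError(f"expected an RGB TIFF, got shape {arr.shape}")
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError(f"expected a non-empty (H, W, 3) RGB raster, got shape {image.shape}")
    return image


def segment_tissue(
    image: np.ndarray,
    downsample: int = 16,
    saturation_floor: float = 0.05,
    closing_radius: int = 2,
    min_object_px: int = 64,
) -> TissueMask:
    """Threshold-based tissue segmentation on the HSV saturation channel.

    The image is mean-pooled by ``downsample``, saturation is thresholded by
    Otsu (clipped below at ``saturation_floor`` so faint uniform scans do not
    split), the mask is morphologically closed with a radius-
    ``closing_radius`` disk, and connected components smaller than
    ``min_object_px`` downsampled pixels are dropped.
    """
    image = _check_rgb(image)
    small = image.astype(float)
    if downsample > 1:
        small = block_reduce(small, (downsample, downsample, 1), np.mean)
    sat = rgb2hsv(small / 255.0)[..., 1]
    if sat.max() - sat.min() < 1e-6:
        thresh = saturation_floor  # constant saturation: Otsu is undefined
    else:
        thresh = max(float(threshold_otsu(sat)), saturation_floor)
    mask = sat > thresh
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    if min_object_px > 0:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return TissueMask(mask=mask, downsample=float(downsample))


def grid_patches(
    mask: TissueMask,
    slide_dims: tuple[int, int],
    tile_size: int = TILE_SIZE,
    min_tissue_fraction: float = 0.5,
    slide_id: str = "slide",
) -> PatchGrid:
    """Retain the grid tiles whose tissue coverage meets ``min_tissue_fraction``.

    ``slide_dims`` is ``(width, height)`` in slide-level pixels. Coverage of a
    tile is the fraction of its footprint covered by the (upsampled) mask.
    Tiles are returned row-major. A slide smaller than one tile yields an
    empty grid with a warning.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if not 0.0 < min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must lie in (0, 1]")
    width, height = slide_dims
    if width < tile_size or height < tile_size:
        warnings.warn(
            f"slide {width}x{height} is smaller than one {tile_size} px tile; empty grid",
            stacklevel=2,
        )
        return PatchGrid(slide_id=slide_id, tiles=np.zeros((0, 2), dtype=int), tile_size=tile_size)

    ds = int(round(mask.downsample))
    full = np.repeat(np.repeat(mask.mask, ds, axis=0), ds, axis=1)
    # pad/crop the upsampled mask to the exact slide footprint (rounding slack)
    canvas = np.zeros((height, width), dtype=bool)
    h = min(height, full.shape[0])
    w = min(width, full.shape[1])
    canvas[:h, :w] = full[:h, :w]

    n_rows = height // tile_size
    n_cols = width // tile_size
    cropped = canvas[: n_rows * tile_size, : n_cols * tile_size]
    coverage = block_reduce(cropped.astype(float), (tile_size, tile_size), np.mean)
    keep_r, keep_c = np.nonzero(coverage >= min_tissue_fraction - 1e-12)
    tiles = np.stack([keep_c * tile_size, keep_r * tile_size], axis=1)  # row-major already
    return PatchGrid(slide_id=slide_id, tiles=tiles, tile_size=tile_size)


def extract_features(
    image: np.ndarray,
    grid: PatchGrid,
    encoder: PatchEncoder,
    sample_id: str | None = None,
) -> FeatureBag:
    """Encode every grid tile of the slide into one row of a FeatureBag.

    Row ``k`` of the result is ``encoder(tile_k)``; coordinates align
    row-for-row with the grid, so the operation is equivariant under tile
    reordering. The encoder must return the same vector length for every
    tile.
    """
    image = _check_rgb(image)
    if len(grid) == 0:
        raise ValueError("cannot extract features from an empty grid")
    ts = grid.tile_size
    rows = []
    dim = None
    for x, y in grid.tiles:
        vec = np.asarray(encoder(image[y : y + ts, x : x + ts]), dtype=float).ravel()
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ValueError(
                f"encoder contract violation: output length changed from {dim} to {vec.size}"
            )
        rows.append(vec)
    return FeatureBag(
        sample_id=sample_id or grid.slide_id,
        features=np.stack(rows),
        coords=grid.tiles.copy(),
        encoder_id=getattr(encoder, "name", type(encoder).__name__),
    )
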