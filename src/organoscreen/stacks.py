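"""Bright-field z-stacks, edge stacks, and z-projections.

A well is imaged as a transmitted-light z-stack spanning the Matrigel dome
(default 50 µm layer spacing, 8-bit gray scale), either as a single position
or as 2-4 tiled positions that are mosaicked into one frame per well.  The
downstream segmentation consumes three projections of the stack:

* ``min``  of the bright-field stack  — organoid rims are dark, so the
  per-pixel minimum concentrates object contrast (used for intensity
  measurements and object classification),
* ``std``  of the per-layer Sobel gradient-magnitude stack — highlights
  pixels that are edge-like in some layer (used for thresholding),
* ``sum``  of the edge stack — the intensity-summary image handed to the
  pixel classifier in the combined workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "BrightfieldStack",
    "EdgeStack",
    "Projection",
    "assemble_stack",
    "mosaic_tiles",
    "sobel_edges",
    "project",
    "read_stack",
    "write_stack",
    "write_projection",
    "read_layout",
]

log = logging.getLogger(__name__)

#: Standard (unnormalized) 3x3 Sobel kernels; gx responds to horizontal
#: intensity change (column direction), gy to vertical.
SOBEL_GX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_GY = SOBEL_GX.T.copy()

LAYOUT_COLUMNS = ("well", "position", "timepoint_h", "treatment", "replicate", "pixel_size_um")


@dataclass
class BrightfieldStack:
    """One well/timepoint bright-field z-stack on the 8-bit scale.

    ``pixels`` is ``(n_layers, height, width)`` with values in ``[0, 255]``.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    layer_spacing_um: float = 50.0
    well_id: str = ""
    position_ids: tuple = (1,)
    timepoint_h: float = 0.0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError(f"stack must be 3-D (layers, H, W), got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1:
            raise ValueError("stack needs at least one layer")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError(
                f"intensities must lie in [0, 255], got range "
                f"[{self.pixels.min():g}, {self.pixels.max():g}]"
            )
        if self.layer_spacing_um <= 0:
            raise ValueError("layer_spacing_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_layers(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class EdgeStack:
    """Per-layer Sobel gradient-magnitude stack (non-negative, same shape as source)."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError("edge stack must be 3-D")
        if self.pixels.min() < 0:
            raise ValueError("edge magnitudes must be non-negative")

    @property
    def n_layers(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class Projection:
    """A 2-D z-projection of a bright-field or edge stack."""

    pixels: np.ndarray
    kind: str
    source_kind: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("projection must be 2-D")
        if self.kind not in ("min", "std", "sum"):
            raise ValueError(f"unknown projection kind {self.kind!r}")
        if self.source_kind not in ("brightfield", "edge"):
            raise ValueError(f"unknown source kind {self.source_kind!r}")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def assemble_stack(layer_images: Sequence[np.ndarray], **metadata) -> BrightfieldStack:
    """Stack per-layer images into a validated :class:`BrightfieldStack`.

    Layer order is preserved.  Inputs outside the 8-bit range are linearly
    rescaled to [0, 255] (logged); mismatched layer shapes raise with the
    offending layer index.
    """
    layers = [np.asarray(im, dtype=np.float64) for im in layer_images]
    if not layers:
        raise ValueError("at least one layer image is required")
    ref_shape = layers[0].shape
    for i, layer in enumerate(layers):
        if layer.ndim != 2:
            raise ValueError(f"layer {i} is not a 2-D image (ndim={layer.ndim})")
        if layer.shape != ref_shape:
            raise ValueError(
                f"layer {i} has shape {layer.shape}, expected {ref_shape} (layer 0)"
            )
    pixels = np.stack(layers, axis=0)
    lo, hi = pixels.min(), pixels.max()
    if lo < 0 or hi > 255:
        span = hi - lo
        pixels = (pixels - lo) * (255.0 / span) if span > 0 else np.zeros_like(pixels)
        log.warning(
            "input intensities in [%g, %g] rescaled linearly to the 8-bit range", lo, hi
        )
    return BrightfieldStack(pixels=pixels, **metadata)


def mosaic_tiles(
    tiles: Sequence[np.ndarray],
    grid_shape: tuple | None = None,
    overlap_px: int = 0,
) -> np.ndarray:
    """Mosaic 2-4 tiled position stacks into one per-well stack.

    Tiles are 3-D ``(layers, H, W)`` arrays placed row-major on a grid;
    ``overlap_px`` is cropped from the leading edge of every non-first tile
    in each grid direction.  No feature-based registration is performed —
    acquisition reuses a fixed automation setup, so grid placement suffices.
    """
    arrs = [np.asarray(t, dtype=np.float64) for t in tiles]
    if not arrs:
        raise ValueError("no tiles given")
    if len(arrs) == 1:
        return arrs[0]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("all tiles must share one shape")
    n = len(arrs)
    if grid_shape is None:
        grid_shape = {2: (1, 2), 3: (1, 3), 4: (2, 2)}.get(n)
        if grid_shape is None:
            raise ValueError(f"cannot infer a grid for {n} tiles; pass grid_shape")
    rows, cols = grid_shape
    if rows * cols != n:
        raise ValueError(f"grid {grid_shape} does not hold {n} tiles")
    row_blocks = []
    for r in range(rows):
        row_tiles = []
        for c in range(cols):
            tile = arrs[r * cols + c]
            if r > 0:
                tile = tile[:, overlap_px:, :]
            if c > 0:
                tile = tile[:, :, overlap_px:]
            row_tiles.append(tile)
        row_blocks.append(np.concatenate(row_tiles, axis=2))
    return np.concatenate(row_blocks, axis=1)


def sobel_edges(stack: BrightfieldStack) -> EdgeStack:
    """Apply the 3x3 Sobel edge detector to each z-layer.

    Returns per-layer gradient magnitude ``sqrt(gx**2 + gy**2)`` with
    reflective border padding; output shape equals input shape.
    """
    out = np.empty_like(stack.pixels)
    for i in range(stack.n_layers):
        layer = stack.pixels[i]
        gx = ndimage.convolve(layer, SOBEL_GX, mode="reflect")
        gy = ndimage.convolve(layer, SOBEL_GY, mode="reflect")
        out[i] = np.hypot(gx, gy)
    return EdgeStack(pixels=out, source_id=stack.well_id)


def project(stack: BrightfieldStack | EdgeStack, kind: str) -> Projection:
    """Project a stack along z: per-pixel ``min``, sample ``std`` (n-1), or ``sum``."""
    if kind not in ("min", "std", "sum"):
        raise ValueError(f"unknown projection kind {kind!r}")
    source_kind = "brightfield" if isinstance(stack, BrightfieldStack) else "edge"
    pixels = stack.pixels
    if kind == "std":
        if pixels.shape[0] < 2:
            raise ValueError("std projection requires at least 2 layers")
        proj = pixels.std(axis=0, ddof=1)
    elif kind == "min":
        proj = pixels.min(axis=0)
    else:
        proj = pixels.sum(axis=0)
    return Projection(pixels=proj, kind=kind, source_kind=source_kind)


# ---------------------------------------------------------------------------
# File I/O: multi-page grayscale TIFF stacks, projection TIFFs, layout CSV.

def write_stack(path: str | Path, stack: BrightfieldStack) -> None:
    """Write a stack as a multi-page 8-bit grayscale TIFF (values rounded)."""
    data = np.clip(np.rint(stack.pixels), 0, 255).astype(np.uint8)
    # explicit photometric: a 3-layer stack must not be guessed as RGB planes
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_stack(path: str | Path, **metadata) -> BrightfieldStack:
    """Read a single- or multi-page grayscale TIFF as a :class:`BrightfieldStack`."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, :, :]
    return assemble_stack(list(data), **metadata)


def write_projection(path: str | Path, projection: Projection) -> None:
    """Write a projection as a 32-bit float TIFF (std/sum exceed 8-bit range)."""
    tifffile.imwrite(str(path), projection.pixels.astype(np.float32))


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read the plate-layout CSV mapping wells to treatment/replicate/timepoint.

    Required columns: well, position, timepoint_h, treatment, replicate,
    pixel_size_um.
    """
    layout = pd.read_csv(path)
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ValueError(f"layout file {path} is missing columns: {missing}")
    return layout
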