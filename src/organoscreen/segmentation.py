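"""Edge-projection segmentation: thresholding, binary cleanup, particle analysis.

This is the simple workflow: binarize the SD-of-edges projection, clean the
mask with an ordered sequence of binary operations, extract connected
components ("particle analysis", 8-connectivity by default), and measure
per-object features on the minimum projection of the bright-field stack.
Interactive mask editing is replaced by a file-based correction image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk

from .stacks import Projection

__all__ = [
    "BinaryMask",
    "LabeledMask",
    "ObjectRecord",
    "DEFAULT_BINARY_OPS",
    "apply_binary_ops",
    "binarize",
    "particle_analysis",
    "apply_manual_correction",
    "measure_objects",
    "records_to_frame",
]

log = logging.getLogger(__name__)

#: Default cleanup sequence applied after thresholding, as (op, radius) pairs.
DEFAULT_BINARY_OPS: tuple = (("close", 2), ("fill_holes", None), ("open", 2))

STRUCTURE_8 = np.ones((3, 3), dtype=bool)
STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class BinaryMask:
    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("binary mask must be 2-D")


@dataclass
class LabeledMask:
    """Consecutively labeled objects: 0 = background, k = object k (1..n_objects)."""

    pixels: np.ndarray
    n_objects: int
    connectivity: int = 8
    border_labels: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int32)
        if self.pixels.ndim != 2:
            raise ValueError("labeled mask must be 2-D")
        labels = np.unique(self.pixels)
        labels = labels[labels > 0]
        if len(labels) != self.n_objects or (
            len(labels) and (labels.min() != 1 or labels.max() != self.n_objects)
        ):
            raise ValueError("labels must be consecutive 1..n_objects")


@dataclass
class ObjectRecord:
    """One segmented organoid candidate with geometry and intensity features."""

    object_id: int
    well_id: str
    timepoint_h: float
    area_px: int
    area_um2: float
    mean_gray: float
    sd_gray: float
    centroid: tuple
    bbox: tuple
    perimeter_px: float
    circularity: float
    solidity: float
    touches_border: bool
    replicate_id: str = ""


def _structuring_element(radius: int) -> np.ndarray:
    return disk(int(radius))


def _apply_ops(mask: np.ndarray, ops: Sequence[tuple]) -> np.ndarray:
    for op in ops:
        name, radius = (op if isinstance(op, (tuple, list)) else (op, None))
        if name == "close":
            mask = ndimage.binary_closing(mask, structure=_structuring_element(radius))
        elif name == "open":
            mask = ndimage.binary_opening(mask, structure=_structuring_element(radius))
        elif name == "dilate":
            mask = ndimage.binary_dilation(mask, structure=_structuring_element(radius))
        elif name == "erode":
            mask = ndimage.binary_erosion(mask, structure=_structuring_element(radius))
        elif name == "fill_holes":
            mask = ndimage.binary_fill_holes(mask)
        else:
            raise ValueError(f"unknown binary operation {name!r}")
    return mask


def apply_binary_ops(mask: np.ndarray, ops: Sequence[tuple]) -> np.ndarray:
    """Apply an ordered (op, radius) cleanup sequence to a boolean mask."""
    return _apply_ops(np.asarray(mask, dtype=bool), ops)


def binarize(
    projection: Projection,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    ops: Sequence[tuple] = DEFAULT_BINARY_OPS,
) -> BinaryMask:
    """Threshold a projection and clean the mask with the given op sequence.

    The intended input is the SD projection of the edge stack; other inputs
    are accepted but logged.  ``method='otsu'`` picks the threshold
    automatically, ``method='fixed'`` requires ``fixed_threshold``.
    A constant projection under Otsu yields an empty mask with a warning.
    """
    if not (projection.kind == "std" and projection.source_kind == "edge"):
        log.info(
            "binarize called on a %s projection of a %s stack (expected std-of-edges)",
            projection.kind,
            projection.source_kind,
        )
    img = projection.pixels
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        threshold = float(fixed_threshold)
    elif method == "otsu":
        if np.ptp(img) == 0:
            log.warning("constant projection: Otsu threshold undefined, returning empty mask")
            return BinaryMask(
                pixels=np.zeros(img.shape, dtype=bool),
                provenance={"method": method, "threshold": None, "ops": list(ops)},
            )
        threshold = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = img > threshold
    mask = _apply_ops(mask, ops)
    return BinaryMask(
        pixels=mask,
        provenance={"method": method, "threshold": threshold, "ops": list(ops)},
    )


def particle_analysis(
    mask: BinaryMask | np.ndarray,
    min_area_px: int = 1,
    max_area_px: int | None = None,
    exclude_border: bool = False,
    connectivity: int = 8,
) -> LabeledMask:
    """Connected-component extraction with a size window.

    Components with area in ``[min_area_px, max_area_px]`` are kept and
    relabeled consecutively in scan order.  Components touching the image
    border are kept but flagged unless ``exclude_border``; an empty result
    is valid.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    structure = STRUCTURE_8 if connectivity == 8 else STRUCTURE_4
    labeled, n = ndimage.label(pixels, structure=structure)
    if n == 0:
        return LabeledMask(pixels=labeled, n_objects=0, connectivity=connectivity)
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    keep = areas >= min_area_px
    if max_area_px is not None:
        keep &= areas <= max_area_px
    border = np.zeros(n, dtype=bool)
    edge_labels = np.unique(
        np.concatenate([labeled[0, :], labeled[-1, :], labeled[:, 0], labeled[:, -1]])
    )
    border[edge_labels[edge_labels > 0] - 1] = True
    if exclude_border:
        keep &= ~border
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1:][keep] = np.arange(1, int(keep.sum()) + 1)
    out = remap[labeled]
    border_labels = frozenset(int(remap[i + 1]) for i in range(n) if keep[i] and border[i])
    return LabeledMask(
        pixels=out,
        n_objects=int(keep.sum()),
        connectivity=connectivity,
        border_labels=border_labels,
    )


def apply_manual_correction(
    labeled: LabeledMask, correction: np.ndarray | str | Path
) -> LabeledMask:
    """Apply a file-based correction image to a labeled mask.

    Correction values: 0 keep, 1 delete the object under the mark,
    2 split-barrier (pixels set to background before components are
    recomputed).  Components are recomputed with the mask's connectivity.
    """
    if isinstance(correction, (str, Path)):
        correction = tifffile.imread(str(correction))
    correction = np.asarray(correction)
    if correction.shape != labeled.pixels.shape:
        raise ValueError(
            f"correction shape {correction.shape} does not match mask {labeled.pixels.shape}"
        )
    pixels = labeled.pixels.copy()
    doomed = np.unique(pixels[(correction == 1) & (pixels > 0)])
    if len(doomed):
        pixels[np.isin(pixels, doomed)] = 0
    pixels[correction == 2] = 0
    return particle_analysis(pixels > 0, min_area_px=1, connectivity=labeled.connectivity)


def measure_objects(
    labeled: LabeledMask,
    min_projection: Projection,
    pixel_size_um: float,
    well_id: str = "",
    timepoint_h: float = 0.0,
    replicate_id: str = "",
) -> list[ObjectRecord]:
    """Measure per-object features on the minimum projection.

    ``mean_gray``/``sd_gray`` are computed only over each object's own
    pixels on the 8-bit min projection; circularity is ``4*pi*area /
    perimeter**2`` (may slightly exceed 1 from rasterization).
    """
    if labeled.pixels.shape != min_projection.shape:
        raise ValueError("labeled mask and projection shapes differ")
    if not (min_projection.kind == "min" and min_projection.source_kind == "brightfield"):
        log.info(
            "measuring intensities on a %s projection of a %s stack (expected min of brightfield)",
            min_projection.kind,
            min_projection.source_kind,
        )
    records = []
    intensity = min_projection.pixels
    for prop in regionprops(labeled.pixels, intensity_image=intensity):
        values = intensity[labeled.pixels == prop.label]
        perimeter = float(prop.perimeter)
        circularity = 4.0 * np.pi * prop.area / perimeter**2 if perimeter > 0 else 1.0
        records.append(
            ObjectRecord(
                object_id=int(prop.label),
                well_id=well_id,
                timepoint_h=timepoint_h,
                replicate_id=replicate_id,
                area_px=int(prop.area),
                area_um2=float(prop.area) * pixel_size_um**2,
                mean_gray=float(values.mean()),
                sd_gray=float(values.std(ddof=0)),
                centroid=tuple(float(c) for c in prop.centroid),
                bbox=tuple(int(b) for b in prop.bbox),
                perimeter_px=perimeter,
                circularity=float(circularity),
                solidity=float(prop.solidity),
                touches_border=int(prop.label) in labeled.border_labels,
            )
        )
    return records


def records_to_frame(records: Sequence[ObjectRecord]) -> pd.DataFrame:
    """Tabulate object records; centroid/bbox are expanded to scalar columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "object_id": r.object_id,
                "well_id": r.well_id,
                "replicate_id": r.replicate_id,
                "timepoint_h": r.timepoint_h,
                "area_px": r.area_px,
                "area_um2": r.area_um2,
                "mean_gray": r.mean_gray,
                "sd_gray": r.sd_gray,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "bbox_min_row": r.bbox[0],
                "bbox_min_col": r.bbox[1],
                "bbox_max_row": r.bbox[2],
                "bbox_max_col": r.bbox[3],
                "perimeter_px": r.perimeter_px,
                "circularity": r.circularity,
                "solidity": r.solidity,
                "touches_border": r.touches_border,
            }
        )
    columns = [
        "object_id", "well_id", "replicate_id", "timepoint_h", "area_px", "area_um2",
        "mean_gray", "sd_gray", "centroid_row", "centroid_col", "bbox_min_row",
        "bbox_min_col", "bbox_max_row", "bbox_max_col", "perimeter_px", "circularity",
        "solidity", "touches_border",
    ]
    return pd.DataFrame(rows, columns=columns)
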