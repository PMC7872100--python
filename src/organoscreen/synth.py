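"""Seeded synthetic-data generators: well scenes with ground truth, CT tables
with known effects.

Scenes emulate 2x bright-field appearance of organoid cultures in a Matrigel
dome: objects are drawn as dark rims on a light background (the segmentation
acts on edge energy, so rim contrast — not photometric realism — is what
matters), each z-layer is defocus-blurred in proportion to its distance from
the focus layer, and Gaussian read noise is added.  Phenotypes follow the
eight-class vocabulary: budding organoids are lobed dark-rimmed shapes with
a mid-gray interior, spheres are thin-rimmed circles with a bright lumen,
clusters are deliberate overlaps of 2-4 organoid shapes, debris are small
dark specks, air bubbles are large dark-ringed circles, and the plate edge
is a thick dark arc crossing an image corner.  Ground-truth areas are exact
rasterized pixel counts.

CT tables emulate the qPCR screen: control wells drawn around per-gene
baseline dCTs, treated wells shifted by a per-treatment log2 effect vector,
Gaussian CT noise per well, optional technical duplicates, and a detection
cutoff above which CTs are reported missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .phenotype import ObjectClass
from .screen_stats import DEFAULT_HOUSEKEEPING, DEFAULT_MARKER_PANEL
from .stacks import BrightfieldStack

__all__ = [
    "SceneSpec",
    "GroundTruthObject",
    "GroundTruth",
    "CtSimSpec",
    "render_scene",
    "make_ct_table",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic well scene."""

    shape: tuple = (384, 384)
    n_layers: int = 5
    focus_layer: int = 2
    # per-class object counts
    n_organoid: int = 6
    n_big_sphere: int = 2
    n_small_sphere: int = 3
    n_cluster: int = 1
    n_debris: int = 3
    n_air_bubble: int = 1
    n_plate_edge: int = 1
    # size ranges (px)
    organoid_lobe_radius: tuple = (9, 14)
    organoid_n_lobes: tuple = (3, 6)
    big_sphere_radius: tuple = (24, 38)
    small_sphere_radius: tuple = (8, 14)
    debris_radius: tuple = (2, 5)
    air_bubble_radius: tuple = (40, 55)
    # appearance (8-bit gray levels)
    background: float = 200.0
    organoid_rim: float = 70.0
    organoid_interior: float = 150.0
    organoid_rim_width: int = 3
    sphere_rim: float = 90.0
    sphere_lumen: float = 225.0
    sphere_rim_width: int = 2
    debris_intensity: float = 30.0
    bubble_ring: float = 25.0
    bubble_interior: float = 235.0
    bubble_ring_width: int = 6
    plate_edge_intensity: float = 60.0
    plate_edge_width: int = 10
    #: minimum clearance between distinct objects (px).  Defocus blur reaches
    #: sigma = blur_coeff * 2 layers in the default stack, and edge features
    #: computed at scale sigma extend ~(2*sigma + 1) px past each boundary, so
    #: rims closer than ~10 px smear into one edge band: such a pair is not
    #: optically resolvable and constitutes a cluster, not two objects.
    min_separation_px: int = 12
    # optics / acquisition
    blur_coeff: float = 1.0  # defocus sigma per layer of distance from focus
    noise_sigma: float = 5.0
    seam_offset: float | None = None  # one-column brightness offset (stitching seam)
    # metadata
    pixel_size_um: float = 4.31
    well_id: str = "synthetic"
    timepoint_h: float = 96.0
    replicate_id: str = "R1"
    seed: int = 0


@dataclass
class GroundTruthObject:
    object_id: int
    object_class: str
    center: tuple
    area_px: int
    interior_intensity: float
    radius: float | None = None


@dataclass
class GroundTruth:
    objects: list
    label_map: np.ndarray
    seed: int

    def count(self, object_class: str | ObjectClass) -> int:
        value = ObjectClass(object_class).value
        return sum(1 for o in self.objects if o.object_class == value)


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without forbidden overlap."""


def _disk_mask(shape: tuple, center: tuple, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _organoid_mask(shape, center, rng, spec: SceneSpec) -> np.ndarray:
    """Union of overlapping lobes around ``center`` (a budding organoid)."""
    k = int(rng.integers(spec.organoid_n_lobes[0], spec.organoid_n_lobes[1] + 1))
    lo, hi = spec.organoid_lobe_radius
    mask = np.zeros(shape, dtype=bool)
    for j in range(k):
        r = float(rng.uniform(lo, hi))
        if j == 0:
            offset = (0.0, 0.0)
        else:
            angle = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0.5, 1.1) * lo
            offset = (dist * np.sin(angle), dist * np.cos(angle))
        mask |= _disk_mask(shape, (center[0] + offset[0], center[1] + offset[1]), r)
    return mask


def _paint_rimmed(canvas, mask, rim_width, rim_value, interior_value):
    interior = ndimage.binary_erosion(mask, structure=disk(rim_width))
    canvas[mask & ~interior] = rim_value
    canvas[interior] = interior_value


def _try_place(occupied, candidate, margin: int) -> bool:
    grown = ndimage.binary_dilation(candidate, structure=disk(margin))
    return not (grown & occupied).any()


def render_scene(spec: SceneSpec) -> tuple[BrightfieldStack, GroundTruth]:
    """Render a seeded well scene and its ground truth.

    Objects never overlap (clusters excepted: they are built as deliberate
    overlaps of organoid shapes and recorded as one object).  Raises
    :class:`PlacementError` after 1000 failed placement attempts.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    canvas = np.full(shape, float(spec.background))
    label_map = np.zeros(shape, dtype=np.int32)
    objects: list[GroundTruthObject] = []
    occupied = np.zeros(shape, dtype=bool)
    next_id = 1

    def register(mask, object_class, center, interior, radius=None):
        nonlocal next_id
        label_map[mask] = next_id
        occupied[mask] = True
        objects.append(
            GroundTruthObject(
                object_id=next_id,
                object_class=ObjectClass(object_class).value,
                center=(float(center[0]), float(center[1])),
                area_px=int(mask.sum()),
                interior_intensity=float(interior),
                radius=radius,
            )
        )
        next_id += 1

    def place(make_mask, object_class, paint, interior, bound, radius=None):
        for _ in range(1000):
            center = (
                float(rng.uniform(bound, shape[0] - bound)),
                float(rng.uniform(bound, shape[1] - bound)),
            )
            mask = make_mask(center)
            if not mask.any():
                continue
            if _try_place(occupied, mask, spec.min_separation_px):
                paint(mask)
                register(mask, object_class, center, interior, radius)
                return
        raise PlacementError(
            f"could not place a {object_class} object after 1000 attempts; "
            "reduce object counts or sizes"
        )

    # Plate edge first (it constrains the border region): a thick arc from a
    # circle centered on a random image corner.
    for _ in range(spec.n_plate_edge):
        corner = (
            float(rng.choice([0, shape[0] - 1])),
            float(rng.choice([0, shape[1] - 1])),
        )
        R = 0.75 * min(shape)
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        dist = np.sqrt((rr - corner[0]) ** 2 + (cc - corner[1]) ** 2)
        mask = (dist >= R - spec.plate_edge_width) & (dist <= R)
        canvas[mask] = spec.plate_edge_intensity
        register(mask, ObjectClass.PLATE_EDGE, corner, spec.plate_edge_intensity)

    for _ in range(spec.n_air_bubble):
        r = float(rng.uniform(*spec.air_bubble_radius))
        place(
            lambda c, r=r: _disk_mask(shape, c, r),
            ObjectClass.AIR_BUBBLE,
            lambda m: _paint_rimmed(
                canvas, m, spec.bubble_ring_width, spec.bubble_ring, spec.bubble_interior
            ),
            spec.bubble_interior,
            bound=r + 4,
            radius=r,
        )

    for _ in range(spec.n_big_sphere):
        r = float(rng.uniform(*spec.big_sphere_radius))
        place(
            lambda c, r=r: _disk_mask(shape, c, r),
            ObjectClass.BIG_SPHERE,
            lambda m: _paint_rimmed(
                canvas, m, spec.sphere_rim_width, spec.sphere_rim, spec.sphere_lumen
            ),
            spec.sphere_lumen,
            bound=r + 4,
            radius=r,
        )

    for _ in range(spec.n_small_sphere):
        r = float(rng.uniform(*spec.small_sphere_radius))
        place(
            lambda c, r=r: _disk_mask(shape, c, r),
            ObjectClass.SMALL_SPHERE,
            lambda m: _paint_rimmed(
                canvas, m, spec.sphere_rim_width, spec.sphere_rim, spec.sphere_lumen
            ),
            spec.sphere_lumen,
            bound=r + 4,
            radius=r,
        )

    for _ in range(spec.n_organoid):
        bound = spec.organoid_lobe_radius[1] * 2.5
        place(
            lambda c: _organoid_mask(shape, c, rng, spec),
            ObjectClass.ORGANOID,
            lambda m: _paint_rimmed(
                canvas, m, spec.organoid_rim_width, spec.organoid_rim, spec.organoid_interior
            ),
            spec.organoid_interior,
            bound=bound,
        )

    for _ in range(spec.n_cluster):
        bound = spec.organoid_lobe_radius[1] * 3.5

        def cluster_mask(center):
            n_members = int(rng.integers(2, 5))
            mask = np.zeros(shape, dtype=bool)
            for j in range(n_members):
                if j == 0:
                    c = center
                else:
                    angle = rng.uniform(0, 2 * np.pi)
                    d = rng.uniform(0.8, 1.6) * spec.organoid_lobe_radius[1]
                    c = (center[0] + d * np.sin(angle), center[1] + d * np.cos(angle))
                mask |= _organoid_mask(shape, c, rng, spec)
            _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), bool))
            return mask if n_comp == 1 else np.zeros(shape, dtype=bool)

        place(
            cluster_mask,
            ObjectClass.CLUSTER,
            lambda m: _paint_rimmed(
                canvas, m, spec.organoid_rim_width, spec.organoid_rim, spec.organoid_interior
            ),
            spec.organoid_interior,
            bound=bound,
        )

    for _ in range(spec.n_debris):
        r = float(rng.uniform(*spec.debris_radius))

        def speck_mask(center, r=r):
            mask = _disk_mask(shape, center, r)
            for _ in range(2):
                angle = rng.uniform(0, 2 * np.pi)
                c = (center[0] + r * np.sin(angle), center[1] + r * np.cos(angle))
                mask |= _disk_mask(shape, c, max(1.0, r * 0.6))
            return mask

        place(
            speck_mask,
            ObjectClass.DEBRIS,
            lambda m: canvas.__setitem__(m, spec.debris_intensity),
            spec.debris_intensity,
            bound=3 * r + 4,
        )

    # z-stack: defocus blur grows with distance from the focus layer, then
    # read noise; values rounded to the 8-bit grid so TIFF round-trips are exact.
    layers = []
    for layer in range(spec.n_layers):
        sigma = spec.blur_coeff * abs(layer - spec.focus_layer)
        img = ndimage.gaussian_filter(canvas, sigma) if sigma > 0 else canvas.copy()
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
        if spec.seam_offset is not None:
            img[:, shape[1] // 2] += spec.seam_offset
        layers.append(np.clip(np.rint(img), 0, 255))
    stack = BrightfieldStack(
        pixels=np.stack(layers),
        pixel_size_um=spec.pixel_size_um,
        well_id=spec.well_id,
        timepoint_h=spec.timepoint_h,
        replicate_id=spec.replicate_id,
    )
    return stack, GroundTruth(objects=objects, label_map=label_map, seed=spec.seed)


# ---------------------------------------------------------------------------
# qPCR screen simulation


def _default_baseline() -> dict:
    return {g: -4.0 for g in DEFAULT_MARKER_PANEL}


@dataclass
class CtSimSpec:
    """Parameters of a synthetic qPCR screen."""

    genes: tuple = DEFAULT_MARKER_PANEL
    housekeeping: str = DEFAULT_HOUSEKEEPING
    housekeeping_ct_mean: float = 20.0
    baseline_dct: Mapping[str, float] = field(default_factory=_default_baseline)
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    calibrator: str = "DMSO"
    noise_sigma: float = 0.25
    n_replicates: int = 4
    n_control_wells: int = 4
    technical_duplicates: bool = True
    technical_sigma: float = 0.05
    detection_cutoff: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def make_ct_table(spec: CtSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format CT table plus the ground-truth effect table.

    Per sample, the housekeeping CT is drawn once (noise shared across that
    sample's genes) and each gene CT is ``ct_hk - dct_true + noise`` where
    ``dct_true = baseline + log2 effect``.  CTs above the detection cutoff
    are reported missing.  Truth lists each treatment's per-gene log2 effect
    and its Euclidean norm over the panel.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []

    def emit(replicate, treatment, well, gene, ct):
        ct_val = np.nan if ct > spec.detection_cutoff else ct
        if spec.technical_duplicates:
            for tech in (1, 2):
                value = ct_val + rng.normal(0.0, spec.technical_sigma)
                rows.append((replicate, treatment, well, tech, gene, value))
        else:
            rows.append((replicate, treatment, well, 1, gene, ct_val))

    treatments = [(spec.calibrator, w) for w in range(1, spec.n_control_wells + 1)]
    treatments += [(t, 1) for t in spec.effects]
    for rep in range(1, spec.n_replicates + 1):
        replicate = f"R{rep}"
        for treatment, well in treatments:
            effect = spec.effects.get(treatment, {})
            ct_hk = spec.housekeeping_ct_mean + rng.normal(0.0, spec.noise_sigma)
            emit(replicate, treatment, well, spec.housekeeping, ct_hk)
            for gene in spec.genes:
                dct_true = spec.baseline_dct.get(gene, -4.0) + float(effect.get(gene, 0.0))
                ct_gene = ct_hk - dct_true + rng.normal(0.0, spec.noise_sigma)
                emit(replicate, treatment, well, gene, ct_gene)

    ct = pd.DataFrame(
        rows, columns=["replicate", "treatment", "well", "technical_rep", "gene", "ct"]
    )
    truth_rows = []
    for treatment in list(spec.effects) + [spec.calibrator]:
        effect = spec.effects.get(treatment, {})
        vec = np.array([float(effect.get(g, 0.0)) for g in spec.genes])
        truth_rows.append(
            {
                "treatment": treatment,
                "true_distance": float(np.sqrt((vec**2).sum())),
                **{f"effect_{g}": float(effect.get(g, 0.0)) for g in spec.genes},
            }
        )
    return ct, pd.DataFrame(truth_rows)
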