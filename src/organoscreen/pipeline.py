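"""End-to-end runs: plate layout -> per-well quantification -> screen stats.

``run_quantify`` walks the plate layout, processes every well/timepoint
stack (assemble -> Sobel edges -> projections -> simple or combined
segmentation -> measurement -> classification -> exclusion), and writes the
per-object table, per-well summaries, and a run manifest.  ``run_screen``
joins the imaging readout with a qPCR CT table into fold changes, the
perturbation ranking, a clustering tree, and the size-vs-expression
correlation.  Outputs are written atomically (write-then-rename) so a
partial failure never corrupts previous results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phenotype import (
    ObjectClass,
    apply_exclusions,
    classify_objects,
    load_model,
    object_feature_table,
    predict_pixel_map,
)
from .screen_stats import (
    DEFAULT_HOUSEKEEPING,
    DEFAULT_MARKER_PANEL,
    DEFAULT_PERTURBATION_THRESHOLD,
    cluster_tree,
    correlate,
    delta_ct,
    fold_change,
    perturbation,
)
from .segmentation import (
    DEFAULT_BINARY_OPS,
    BinaryMask,
    apply_binary_ops,
    apply_manual_correction,
    binarize,
    measure_objects,
    particle_analysis,
    records_to_frame,
)
from .stacks import (
    BrightfieldStack,
    mosaic_tiles,
    project,
    read_layout,
    read_stack,
    sobel_edges,
)

__all__ = ["RunConfig", "run_quantify", "run_screen", "stack_filename"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a quantification/screen run (loadable from YAML)."""

    input_root: str = "."
    output_root: str = "out"
    layout: str = "layout.csv"
    mode: str = "simple"  # "simple" (threshold) or "combined" (classifier)
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    # Default cleanup appends erode(1) to the close/fill/open sequence: the
    # Sobel response of a rim extends one pixel beyond the object boundary,
    # and the erosion removes that halo so measured areas are unbiased.
    binary_ops: list = field(
        default_factory=lambda: [list(op) for op in DEFAULT_BINARY_OPS] + [["erode", 1]]
    )
    # Combined mode: the outline-probability band is already continuous, and
    # closing it would bridge adjacent objects, so no close step here.
    combined_binary_ops: list = field(
        default_factory=lambda: [["fill_holes", None], ["open", 2]]
    )
    min_area_px: int = 200
    max_area_px: int | None = None
    exclude_border: bool = False
    connectivity: int = 8
    overlap_px: int = 0
    pixel_model: str | None = None
    object_model: str | None = None
    # Outline pixels are predicted with high confidence; the band between
    # two adjacent rims hovers near 0.5, so thresholding slightly above it
    # keeps neighboring objects separate.
    pixel_threshold: float = 0.6
    corrections_dir: str | None = None
    housekeeping: str = DEFAULT_HOUSEKEEPING
    calibrator: str = "DMSO"
    marker_genes: list = field(default_factory=lambda: list(DEFAULT_MARKER_PANEL))
    exclude_genes: list = field(default_factory=list)
    exclude_treatments: list = field(default_factory=list)
    perturbation_threshold: float = DEFAULT_PERTURBATION_THRESHOLD
    expression_gene: str = "Lgr5"
    expression_scale: str = "xfold"  # or "log2"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        """Fail fast: every referenced file must exist before processing."""
        if self.mode not in ("simple", "combined"):
            raise ValueError(f"unknown mode {self.mode!r}")
        layout = Path(self.input_root) / self.layout
        if not layout.exists() and not Path(self.layout).exists():
            raise FileNotFoundError(f"layout file not found: {self.layout}")
        if self.mode == "combined":
            for name in ("pixel_model", "object_model"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"combined mode requires {name}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")

    def layout_path(self) -> Path:
        direct = Path(self.layout)
        return direct if direct.exists() else Path(self.input_root) / self.layout


def stack_filename(well: str, timepoint_h: float, position: int) -> str:
    """Canonical stack filename: ``<well>_t<timepoint>h_p<position>.tif``."""
    return f"{well}_t{timepoint_h:g}h_p{int(position)}.tif"


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _atomic_write_csv(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    frame.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _atomic_write_text(text: str, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


@dataclass
class QuantifyResult:
    objects: pd.DataFrame
    objects_post: pd.DataFrame
    well_summaries: pd.DataFrame
    missing_wells: list
    failed_wells: list

    @property
    def exit_code(self) -> int:
        if self.failed_wells:
            return 1
        return 2 if self.missing_wells else 0


def quantify_stack(stack, config: RunConfig, pixel_model=None, object_model=None):
    """Run the per-well part of the pipeline on an in-memory stack.

    Returns ``(objects_frame, objects_post_exclusion, labeled, extras)``
    where the frames carry measurement plus (in combined mode) phenotype
    columns.
    """
    edges = sobel_edges(stack)
    min_proj = project(stack, "min")
    sd_proj = project(edges, "std")
    pmap = None
    if config.mode == "combined":
        ops = [tuple(op) for op in config.combined_binary_ops]
        sum_proj = project(edges, "sum")
        pmap = predict_pixel_map(pixel_model, sum_proj)
        mask = BinaryMask(
            pixels=apply_binary_ops(pmap >= config.pixel_threshold, ops),
            provenance={"method": "pixel_model", "threshold": config.pixel_threshold, "ops": ops},
        )
    else:
        ops = [tuple(op) for op in config.binary_ops]
        mask = binarize(
            sd_proj, method=config.threshold_method,
            fixed_threshold=config.fixed_threshold, ops=ops,
        )
    labeled = particle_analysis(
        mask,
        min_area_px=config.min_area_px,
        max_area_px=config.max_area_px,
        exclude_border=config.exclude_border,
        connectivity=config.connectivity,
    )
    if config.corrections_dir:
        correction = Path(config.corrections_dir) / (
            f"{stack.well_id}_t{stack.timepoint_h:g}h_correction.tif"
        )
        if correction.exists():
            labeled = apply_manual_correction(labeled, correction)
    records = measure_objects(
        labeled,
        min_proj,
        pixel_size_um=stack.pixel_size_um,
        well_id=stack.well_id,
        timepoint_h=stack.timepoint_h,
        replicate_id=stack.replicate_id,
    )
    objects = records_to_frame(records)
    if config.mode == "combined":
        features = object_feature_table(objects, labeled.pixels, pmap)
        classified = classify_objects(object_model, features)
        objects = pd.concat([objects, classified], axis=1)
        post = apply_exclusions(objects, stack.timepoint_h)
    else:
        objects["predicted_class"] = "unclassified"
        post = objects
    return objects, post, labeled, {"pixel_map": pmap, "mask": mask, "min_projection": min_proj}


def _summarize_well(meta: dict, objects: pd.DataFrame, post: pd.DataFrame) -> dict:
    row = dict(meta)
    row["n_objects_pre"] = len(objects)
    row["n_objects_post"] = len(post)
    for cls in ObjectClass:
        row[f"n_{cls.value}"] = int((objects["predicted_class"] == cls.value).sum())
    row["median_area_um2"] = float(post["area_um2"].median()) if len(post) else np.nan
    row["total_area_um2"] = float(post["area_um2"].sum()) if len(post) else 0.0
    row["median_mean_gray"] = float(post["mean_gray"].median()) if len(post) else np.nan
    return row


def run_quantify(config: RunConfig) -> QuantifyResult:
    """Quantify every well/timepoint listed in the plate layout.

    Missing stacks are recorded and the run continues; per-well failures are
    recorded likewise and surfaced through ``exit_code``.
    """
    config.validate()
    layout = read_layout(config.layout_path())
    pixel_model = load_model(config.pixel_model) if config.mode == "combined" else None
    object_model = load_model(config.object_model) if config.mode == "combined" else None
    input_root = Path(config.input_root)
    out_root = Path(config.output_root)

    all_objects, all_post, summaries = [], [], []
    missing_wells, failed_wells = [], []
    input_hashes = {}
    groups = layout.groupby(["well", "timepoint_h"], sort=True)
    for (well, timepoint), group in groups:
        paths = []
        absent = False
        for position in sorted(group["position"].unique()):
            path = input_root / stack_filename(well, timepoint, position)
            if not path.exists():
                missing_wells.append(
                    {"well": str(well), "timepoint_h": float(timepoint), "file": str(path)}
                )
                absent = True
                break
            paths.append(path)
        if absent:
            continue
        meta_row = group.iloc[0]
        try:
            tiles = [read_stack(p).pixels for p in paths]
            for p in paths:
                input_hashes[str(p)] = _sha256(p)
            pixels = mosaic_tiles(tiles, overlap_px=config.overlap_px) if len(tiles) > 1 else tiles[0]
            stack = BrightfieldStack(
                pixels=pixels,
                pixel_size_um=float(meta_row["pixel_size_um"]),
                well_id=str(well),
                timepoint_h=float(timepoint),
                replicate_id=str(meta_row["replicate"]),
            )
            objects, post, _, _ = quantify_stack(
                stack, config, pixel_model=pixel_model, object_model=object_model
            )
        except Exception as exc:  # per-file failure: record, continue
            log.error("well %s t=%s failed: %s", well, timepoint, exc)
            failed_wells.append(
                {"well": str(well), "timepoint_h": float(timepoint), "error": str(exc)}
            )
            continue
        for frame in (objects, post):
            frame["treatment"] = str(meta_row["treatment"])
            frame["replicate"] = str(meta_row["replicate"])
        meta = {
            "well": str(well),
            "treatment": str(meta_row["treatment"]),
            "replicate": str(meta_row["replicate"]),
            "timepoint_h": float(timepoint),
        }
        if len(post) == 0:
            log.warning("well %s t=%s has no objects after exclusions", well, timepoint)
        summaries.append(_summarize_well(meta, objects, post))
        all_objects.append(objects)
        all_post.append(post)

    empty_cols = ["object_id", "well_id", "treatment", "replicate", "timepoint_h"]
    objects_frame = (
        pd.concat(all_objects, ignore_index=True) if all_objects else pd.DataFrame(columns=empty_cols)
    )
    post_frame = (
        pd.concat(all_post, ignore_index=True) if all_post else pd.DataFrame(columns=empty_cols)
    )
    summary_frame = pd.DataFrame(summaries)
    if len(summary_frame):
        summary_frame = summary_frame.sort_values(["well", "timepoint_h"]).reset_index(drop=True)

    _atomic_write_csv(objects_frame, out_root / "objects.csv")
    _atomic_write_csv(post_frame, out_root / "objects_post_exclusion.csv")
    _atomic_write_csv(summary_frame, out_root / "well_summary.csv")
    manifest = {
        "organoscreen_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "input_hashes": input_hashes,
        "missing_wells": missing_wells,
        "failed_wells": failed_wells,
        "outputs": ["objects.csv", "objects_post_exclusion.csv", "well_summary.csv"],
    }
    _atomic_write_text(yaml.safe_dump(manifest, sort_keys=True), out_root / "manifest.yaml")
    return QuantifyResult(
        objects=objects_frame,
        objects_post=post_frame,
        well_summaries=summary_frame,
        missing_wells=missing_wells,
        failed_wells=failed_wells,
    )


@dataclass
class ScreenResult:
    fold_changes: pd.DataFrame
    perturbation: pd.DataFrame
    correlation: dict
    newick: str


def run_screen(
    config: RunConfig,
    ct_csv: str | Path,
    quantify_dir: str | Path | None = None,
) -> ScreenResult:
    """Compute the screen readout from a CT table plus quantification output.

    Writes fold_change.csv, perturbation.csv, cluster_tree.nwk, and
    correlation.yaml under the output root.  Treatments present in only one
    of the imaging/expression inputs are reported and left out of the join.
    """
    out_root = Path(config.output_root)
    quantify_dir = Path(quantify_dir) if quantify_dir is not None else out_root
    ct = pd.read_csv(ct_csv)
    dct = delta_ct(ct, housekeeping=config.housekeeping)
    fc = fold_change(dct, calibrator=config.calibrator)
    scores = perturbation(
        fc,
        marker_genes=config.marker_genes,
        exclude_genes=config.exclude_genes,
        exclude_treatments=config.exclude_treatments,
        threshold=config.perturbation_threshold,
    )
    genes_used = list(scores.attrs["genes_used"])
    medians = fc[genes_used].groupby(level="treatment", sort=True).median()
    log2_matrix = np.log2(medians)
    ranked = log2_matrix.loc[~log2_matrix.index.isin(set(config.exclude_treatments))]
    newick = cluster_tree(ranked).to_newick() if len(ranked) >= 2 else ""

    correlation = {"r": float("nan"), "p": float("nan"), "n": 0}
    summary_path = quantify_dir / "well_summary.csv"
    unmatched: dict = {}
    if summary_path.exists():
        summaries = pd.read_csv(summary_path)
        latest = summaries["timepoint_h"].max()
        size = (
            summaries[summaries["timepoint_h"] == latest]
            .groupby("treatment")["median_area_um2"]
            .median()
        )
        gene = config.expression_gene
        if gene in fc.columns:
            expr = fc[gene].groupby(level="treatment").median()
            if config.expression_scale == "log2":
                expr = np.log2(expr)
            shared = sorted(set(size.index) & set(expr.index))
            unmatched = {
                "imaging_only": sorted(set(size.index) - set(expr.index)),
                "expression_only": sorted(set(expr.index) - set(size.index)),
            }
            if unmatched["imaging_only"] or unmatched["expression_only"]:
                log.warning("treatments present in only one input: %s", unmatched)
            if len(shared) >= 3:
                r, p = correlate(size.loc[shared], expr.loc[shared])
                correlation = {"r": r, "p": p, "n": len(shared)}
            correlation.update(
                {"gene": gene, "scale": config.expression_scale, "timepoint_h": float(latest)}
            )
    else:
        log.warning("no quantification summary at %s; correlation skipped", summary_path)
    correlation["unmatched_treatments"] = unmatched

    fc_out = fc.reset_index()
    _atomic_write_csv(fc_out, out_root / "fold_change.csv")
    _atomic_write_csv(scores, out_root / "perturbation.csv")
    _atomic_write_text(newick + "\n", out_root / "cluster_tree.nwk")
    _atomic_write_text(yaml.safe_dump(correlation, sort_keys=True), out_root / "correlation.yaml")
    return ScreenResult(
        fold_changes=fc, perturbation=scores, correlation=correlation, newick=newick
    )
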