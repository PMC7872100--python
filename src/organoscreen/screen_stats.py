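"""Screen readout statistics.

qRT-PCR relative quantification follows the comparative-CT scheme:
``dCT = CT(housekeeping) - CT(gene)`` (so higher values mean higher relative
expression), ``ddCT`` is the dCT relative to a calibrator treatment (vehicle
control, matched per biological replicate by default), and the fold change
is ``xfold = 2**ddCT``.  A treatment's "perturbation" of a lineage-marker
panel is the Euclidean norm of the per-gene log2 median fold changes;
treatments with log2(perturbation) at or above 1.5 are flagged for
follow-up.  The module also provides Euclidean complete-linkage clustering
trees, Pearson size-vs-expression correlation, type-7 boxplot summaries,
and the well -> replicate -> treatment median-area timecourse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "DEFAULT_HOUSEKEEPING",
    "DEFAULT_MARKER_PANEL",
    "DEFAULT_PERTURBATION_THRESHOLD",
    "DistributionSummary",
    "ClusterTree",
    "delta_ct",
    "fold_change",
    "perturbation",
    "cluster_tree",
    "correlate",
    "summarize_distribution",
    "median_timecourse",
]

log = logging.getLogger(__name__)

DEFAULT_HOUSEKEEPING = "Hprt"

#: Default intestinal-epithelial lineage marker panel (stem, enterocyte,
#: Paneth, goblet, enteroendocrine, and tuft markers); editable.
DEFAULT_MARKER_PANEL = (
    "Lgr5", "Alpi", "Lyz1", "Defa22", "Muc2", "Muc4",
    "Ccl6", "Chga", "Neurod1", "Dclk1", "Trpm5", "Gfi1b",
)

DEFAULT_PERTURBATION_THRESHOLD = 1.5

CT_COLUMNS = ("replicate", "treatment", "gene", "ct")


@dataclass
class DistributionSummary:
    """Boxplot statistics: type-7 quartiles, 1.5*IQR whiskers clipped to data."""

    n: int
    q25: float
    q50: float
    q75: float
    whisker_low: float
    whisker_high: float
    outlier_count: int


@dataclass
class ClusterTree:
    """Agglomerative clustering result: linkage matrix, labels, leaf order."""

    linkage: np.ndarray
    labels: tuple
    leaf_order: tuple

    def to_newick(self) -> str:
        """Render the tree as Newick text with branch lengths from merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def _normalize_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"CT table is missing columns: {missing}")
    ct = ct.copy()
    if "well" not in ct.columns:
        ct["well"] = 1
    bad = ct["ct"].dropna()
    if len(bad) and ((bad <= 0) | (bad > 45)).any():
        raise ValueError("CT values must lie in (0, 45] or be missing")
    return ct


def delta_ct(ct: pd.DataFrame, housekeeping: str = DEFAULT_HOUSEKEEPING) -> pd.DataFrame:
    """Compute dCT = CT(housekeeping) - CT(gene) per sample.

    Input is a long CT table with columns ``replicate, treatment, gene, ct``
    plus optional ``well`` and ``technical_rep``.  Technical replicates are
    averaged (arithmetic mean of available CTs) before subtraction.  Missing
    CTs stay missing; samples lacking the housekeeping CT get all-missing
    dCTs with a warning.  Returns a wide frame indexed by
    ``(replicate, treatment, well)`` with one column per gene.
    """
    ct = _normalize_ct(ct)
    mean_ct = (
        ct.groupby(["replicate", "treatment", "well", "gene"], sort=True)["ct"]
        .mean()
        .unstack("gene")
    )
    if housekeeping not in mean_ct.columns:
        raise ValueError(f"housekeeping gene {housekeeping!r} not in CT table")
    hk = mean_ct[housekeeping]
    n_missing_hk = int(hk.isna().sum())
    if n_missing_hk:
        log.warning(
            "%d sample(s) lack a housekeeping CT; their dCT values are missing", n_missing_hk
        )
    dct = (-mean_ct).add(hk, axis=0)  # hk - gene, NaN-propagating
    return dct


def fold_change(
    dct: pd.DataFrame,
    calibrator: str = "DMSO",
    aggregation: str = "per_replicate_control",
) -> pd.DataFrame:
    """Fold change 2**ddCT relative to a calibrator treatment.

    The default ``per_replicate_control`` aggregation references each
    biological replicate's own calibrator wells (mean dCT over the control
    quadruplicate); ``global`` pools all calibrator wells.  Multi-well
    treatments are averaged (mean dCT) within a replicate first, so the
    calibrator's own ddCT is exactly zero per replicate.  Returns a wide
    frame indexed by ``(replicate, treatment)``; ``attrs['calibrator']``
    records the reference.
    """
    if aggregation not in ("per_replicate_control", "global"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    treatments = dct.index.get_level_values("treatment")
    if calibrator not in set(treatments):
        raise ValueError(f"calibrator treatment {calibrator!r} not present")
    sample_dct = dct.groupby(level=["replicate", "treatment"], sort=True).mean()
    cal = sample_dct.xs(calibrator, level="treatment")
    if aggregation == "global":
        ref = cal.mean(axis=0)
        ddct = sample_dct - ref
    else:
        parts = []
        for rep, block in sample_dct.groupby(level="replicate", sort=True):
            if rep in cal.index:
                parts.append(block - cal.loc[rep])
            else:
                log.warning("replicate %r has no calibrator wells; fold changes missing", rep)
                parts.append(block * np.nan)
        ddct = pd.concat(parts)
    xfold = 2.0**ddct
    xfold.attrs["calibrator"] = f"{calibrator} ({aggregation})"
    return xfold


def perturbation(
    fc: pd.DataFrame,
    marker_genes: Sequence[str] = DEFAULT_MARKER_PANEL,
    exclude_genes: Sequence[str] = (),
    exclude_treatments: Sequence[str] = (),
    threshold: float = DEFAULT_PERTURBATION_THRESHOLD,
) -> pd.DataFrame:
    """Euclidean perturbation of the marker panel per treatment.

    For each treatment, the per-gene median fold change across biological
    replicates is taken; the score is ``sqrt(sum_g log2(median xfold_g)**2)``
    over the genes used.  Genes listed in ``exclude_genes`` (for instance a
    marker below the detection limit) or with any missing median are
    dropped (warned).  Treatments in ``exclude_treatments`` are reported but
    marked excluded from the ranking.  ``flagged_followup`` is True iff
    ``log2(distance) >= threshold``; a zero distance reports a missing
    log2_distance rather than -inf.
    """
    genes = [g for g in marker_genes if g not in set(exclude_genes)]
    genes = [g for g in genes if g in fc.columns]
    if not genes:
        raise ValueError("no marker genes left after exclusions")
    medians = fc[genes].groupby(level="treatment", sort=True).median()
    usable = [g for g in genes if not medians[g].isna().any()]
    dropped = sorted(set(genes) - set(usable))
    if dropped:
        log.warning("genes dropped for missing medians: %s", dropped)
    if not usable:
        raise ValueError("no marker genes with complete medians")
    log2_med = np.log2(medians[usable])
    distance = np.sqrt((log2_med**2).sum(axis=1))
    with np.errstate(divide="ignore"):
        log2_distance = np.where(distance > 0, np.log2(distance.to_numpy()), np.nan)
    out = pd.DataFrame(
        {
            "treatment": medians.index,
            "distance": distance.to_numpy(),
            "log2_distance": log2_distance,
            "n_genes": len(usable),
            "flagged_followup": np.where(
                np.isnan(log2_distance), False, log2_distance >= threshold
            ),
            "excluded_from_ranking": medians.index.isin(set(exclude_treatments)),
        }
    ).reset_index(drop=True)
    out.loc[out["excluded_from_ranking"], "flagged_followup"] = False
    out.attrs["genes_used"] = tuple(usable)
    out.attrs["threshold"] = float(threshold)
    return out


def cluster_tree(matrix: pd.DataFrame, method: str = "complete") -> ClusterTree:
    """Agglomerative clustering of rows on pairwise Euclidean distances.

    Requires at least two rows and no missing values; ties are broken by
    row order (deterministic).
    """
    if len(matrix) < 2:
        raise ValueError("clustering requires at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values; impute or exclude upstream")
    Z = hierarchy.linkage(values, method=method, metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return ClusterTree(
        linkage=Z,
        labels=tuple(str(i) for i in matrix.index),
        leaf_order=tuple(int(i) for i in order),
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df) for paired values.

    Returns ``(nan, nan)`` when either input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if len(x) < 3:
        raise ValueError("correlation requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero variance input: Pearson r undefined")
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))


def summarize_distribution(values: Sequence[float]) -> DistributionSummary:
    """Boxplot summary: type-7 (linear interpolation) quartiles and
    1.5*IQR whiskers clipped to the most extreme observed data inside the
    fences; values beyond are counted as outliers."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.isfinite(arr).all():
        raise ValueError("values must be finite")
    q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q75 - q25
    lo_fence = q25 - 1.5 * iqr
    hi_fence = q75 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return DistributionSummary(
        n=int(arr.size),
        q25=float(q25),
        q50=float(q50),
        q75=float(q75),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outlier_count=int(arr.size - inside.size),
    )


def median_timecourse(objects: pd.DataFrame, value: str = "area_um2") -> pd.DataFrame:
    """Three-level median area table: per well, per replicate, per treatment.

    Objects must carry ``treatment, replicate, well_id, timepoint_h`` plus
    the value column.  Medians are nested: per well, then across wells of a
    replicate, then across replicates; all three levels are returned in one
    tidy frame with a ``level`` column.
    """
    required = {"treatment", "replicate", "well_id", "timepoint_h", value}
    missing = required - set(objects.columns)
    if missing:
        raise ValueError(f"objects frame is missing columns: {sorted(missing)}")
    well = (
        objects.groupby(["treatment", "replicate", "well_id", "timepoint_h"], sort=True)[value]
        .median()
        .rename("median_value")
        .reset_index()
    )
    rep = (
        well.groupby(["treatment", "replicate", "timepoint_h"], sort=True)["median_value"]
        .median()
        .reset_index()
    )
    treat = (
        rep.groupby(["treatment", "timepoint_h"], sort=True)["median_value"]
        .median()
        .reset_index()
    )
    well["level"] = "well"
    rep["level"] = "replicate"
    rep["well_id"] = pd.NA
    treat["level"] = "treatment"
    treat["well_id"] = pd.NA
    treat["replicate"] = pd.NA
    cols = ["level", "treatment", "replicate", "well_id", "timepoint_h", "median_value"]
    return pd.concat([well[cols], rep[cols], treat[cols]], ignore_index=True)
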