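# Methods

## Scope and model of the data

`organoscreen` quantifies heterogeneous intestinal-organoid cultures from
bright-field z-stacks acquired over a whole extracellular-matrix (Matrigel)
dome, and computes the downstream screen readout from qRT-PCR CT tables.
The imaging model is transmitted light at low magnification: organoids at
different depths are in focus in different layers, organoid rims are dark
against a light background, and a well is covered either by one position or
by 2–4 tiled positions mosaicked on a fixed grid (no feature-based
registration — screen acquisition reuses one automation setup per plate, so
tile placement is constant).

Three projections of each stack drive the analysis:

* **min** of the bright-field stack — rims are dark, so the per-pixel
  minimum concentrates object contrast; all intensity features (mean gray
  value, 8-bit scale) are measured here.
* **std of the edge stack** — a per-layer 3×3 Sobel gradient magnitude
  (`sqrt(gx² + gy²)`, reflective padding) followed by a per-pixel sample
  standard deviation (n−1) across layers. A pixel that is edge-like in
  *some* layer scores high; this is the thresholding input of the simple
  workflow.
* **sum of the edge stack** — the intensity-summary image handed to the
  pixel classifier in the combined workflow. Sum was chosen over mean; the
  two differ by a constant factor and classify identically.

## Simple (threshold) workflow

Otsu's threshold on the SD-of-edges projection (a fixed threshold is
configurable; a constant projection yields an empty mask with a warning),
followed by an ordered binary cleanup and connected-component "particle
analysis" (8-connectivity, ImageJ's convention; 4-connectivity available),
with an area window and optional border exclusion. Border-touching objects
are kept but flagged — the dome is mostly interior, and exclusion is a
downstream choice. Manual mask editing is replaced by a file-based
correction image (0 keep / 1 delete object / 2 split barrier).

The module-level default cleanup is close(2) → fill_holes → open(2). The
pipeline default appends **erode(1)**: the Sobel response of a dark rim
extends one pixel beyond the true object boundary, and filling the
thresholded edge band therefore dilates objects by about one pixel —
a +7% area bias for a radius-20 disc. Calibration on noise-free synthetic
scenes shows the single erosion reduces the bias below 0.2% without
affecting counts. All radii and the sequence itself are configuration
values.

## Combined (two-stage classifier) workflow

Stage one is a supervised pixel classifier (random forest, 100 trees,
seeded) over a per-scale filter bank on the edge-sum projection: Gaussian
smoothed intensity, gradient magnitude, Laplacian, and both structure-tensor
eigenvalues, at scales σ ∈ {1, 2} by default (5 features per scale). Two
fine scales are deliberate: σ = 4 features smear the outline response across
the gap between adjacent objects and cause merges, with no accuracy gain.
Training annotations are sparse (outline band vs background pixels);
training images are excluded from every evaluation set.

The outline-probability map is thresholded at **0.6** by default
(configurable). Genuine rim pixels are predicted near 1, while the band
between two neighboring rims — where both objects contribute edge energy —
hovers around 0.5; thresholding slightly above 0.5 keeps neighbors separate
without breaking outline continuity. The mask is then cleaned with
fill_holes → open(2) (no closing: the predicted band is already continuous,
and closing bridges neighbors) and passed to the same particle analysis.

Stage two classifies each measured object into eight phenotype classes —
organoid, big sphere, small sphere, cluster, debris, background mislabeled
as organoid, air bubble, plate edge — from area, mean and SD gray on the
min projection, perimeter, circularity (4π·area/perimeter²), solidity, and
the mean outline probability over the object's pixels (random forest, 100
trees, seeded). The training API accepts any subset of classes so new
phenotypes can be added; a new class must state its own exclusion policy.

**Exclusion policy.** Background-mislabeled, air-bubble, and plate-edge
objects are removed at every timepoint. Debris and cluster objects are
removed from 72 h onward (inclusive: at 72 h and later): early after
seeding genuine single organoids are small and clusters rare, so these
classes carry signal, while at 72–96 h they contaminate the size readout.
The operation is idempotent and monotone in time (the late retained set is
a subset of the early one).

## Screen statistics

Relative expression follows the comparative-CT scheme with Hprt as the
default housekeeping gene: technical duplicates are averaged (arithmetic
mean of available CTs), ΔCT = CT(housekeeping) − CT(gene) so that higher
values mean higher expression, ΔΔCT is referenced to the calibrator
treatment — by default each biological replicate's own DMSO control wells
(mean ΔCT of the quadruplicate; a global pooled calibrator is available) —
and xfold = 2^ΔΔCT. Multi-well treatments are mean-aggregated within a
replicate before referencing, which makes the calibrator's own ΔΔCT exactly
zero per replicate. Missing CTs (below detection) propagate as missing,
never as zero.

A treatment's **perturbation** of the 12-gene intestinal-epithelial lineage
marker panel (Lgr5, Alpi, Lyz1, Defa22, Muc2, Muc4, Ccl6, Chga, Neurod1,
Dclk1, Trpm5, Gfi1b — an editable default) is the Euclidean norm of the
per-gene log2 median fold change across biological replicates. Genes may be
excluded up front (e.g. a marker below the detection limit, as Defa22 can
be) and genes with a missing median are dropped with a warning. Treatments
with log2(distance) ≥ 1.5 are flagged for follow-up (ties flag); a zero
distance reports a missing log2, never −∞. Clustering trees over the log2
median matrix use complete-linkage agglomeration on Euclidean distances
(deterministic tie-breaking by row order) and are exported as Newick text.

Size–expression integration reports the Pearson product-moment correlation
(two-sided p from the t distribution, n−2 df) between per-treatment median
organoid area and per-treatment median relative expression; the expression
scale (xfold or log2 xfold) is recorded in the output. Distribution
summaries use type-7 (linear interpolation) quantiles with 1.5×IQR whiskers
clipped to the most extreme observed values inside the fences, so boxplot
statistics are bit-reproducible. Median timecourses are nested medians:
per well → across wells of a replicate → across replicates, with all three
levels retained.

## Synthetic data

The generators are pure functions of their spec (including the seed) and
stand in for deposited screen data. Scenes draw phenotypes by their
segmentation-relevant signature rather than photometric realism: budding
organoids as unions of 3–6 overlapping lobes with a dark rim and mid-gray
interior; spheres as thin-rimmed circles with bright lumina; clusters as
deliberate overlaps of 2–4 organoid shapes (large area, low solidity);
debris as small dark specks; air bubbles as large dark-ringed circles;
the plate edge as a thick dark arc across an image corner. Ground-truth
areas are exact rasterized pixel counts. Each layer is blurred with
σ = blur_coeff × |layer − focus_layer| (defocus) before Gaussian read noise
(default σ = 5 gray levels) is added; an optional one-column brightness
offset emulates a stitching seam.

Distinct (non-cluster) objects keep a minimum clearance of 12 px. With the
default optics the defocus blur reaches σ = 2 at the outer layers, and
edge features computed at scale σ extend ~(2σ + 1) px past each boundary,
so rims with gaps below ~10 px smear into a single edge band; such pairs
are not optically resolvable and in this imaging model *are* a cluster.
The generator therefore treats "separate objects" as objects resolvable in
principle (12 px = 2×(2σ + 1) plus margin). Scenes that cannot be packed
after 1000 placement attempts raise an error instead of silently violating
the no-overlap invariant.

CT tables simulate the screen design: per biological replicate, a DMSO
calibrator quadruplicate and one well per treated probe; a per-sample
housekeeping CT draw shared across that sample's genes; gene CTs at
baseline ΔCT plus the treatment's log2 effect, with N(0, σ²) noise per well
per gene (default σ_CT = 0.25); optional technical duplicates with small
independent jitter (σ = 0.05); CTs above the detection cutoff (default 40)
reported missing. Because effects enter ΔCT in log2 units, the true
perturbation of a probe is exactly the Euclidean norm of its effect vector,
which makes parameter recovery directly checkable.

What the generators do *not* emulate: uneven illumination and vignetting,
Matrigel refraction, organoid growth between timepoints, intensity
textures inside organoids, qPCR efficiency differences between assays, and
pipetting batch effects. Passing tests therefore demonstrate correctness of
the algorithms under controlled optics and noise, not robustness to every
artifact of real microscopes or real qPCR plates.

## Numerical and reproducibility choices

Projections use float64 throughout; stacks written to TIFF are rounded to
the 8-bit grid, so write/read round-trips are exact. Both classifiers are
seeded random forests; given identical inputs, configuration, and seeds the
full pipeline is bit-reproducible, and output CSVs from repeated runs are
byte-identical. Outputs are written via write-then-rename so an interrupted
run never corrupts earlier results. Degenerate inputs have defined
behavior: constant projections yield empty masks with a warning, empty
particle-analysis results are valid, a single-class object training set
produces an always-that-class model with a warning, zero-variance inputs to
the correlation return missing rather than raising.

Problem sizes used by the test-suite and the acceptance script — 384×384
scenes with 5 layers, 10 training + 10 held-out scenes for classification,
20 sphere scenes for segmentation recovery, 20 simulated probes with 4
biological replicates — were chosen as the smallest sizes at which the
recovery properties are meaningfully exercised, and run on a single CPU in
a few minutes.

## Known limitations

Touching organoids are not split (no watershed); they are handled by the
cluster class, matching the screening interpretation that a merged blob is
not a reliable single-object measurement. Objects closer than the optical
blur are fundamentally unresolvable for any edge-based method. The object
feature list for stage two is this package's own (the interactive tools it
emulates do not publish theirs). The qPCR module performs no efficiency
correction; fold changes assume ideal doubling per cycle.
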