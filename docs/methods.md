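# Methods

## The measurement model

The pipeline quantifies, per β-cell instance and per z-plane, the insulin
signal at the cell's vascular face (where it contacts the capillary basement
membrane, marked by laminin) and at its avascular face, and tests the paired
difference across cells. The procedure is deliberately windowed and
rank-based rather than model-fitted:

- **Boundary region.** For each cell mask `M`, the region is the Euclidean
  binary dilation of `M` by a disc of radius `boundary_width_px` (default
  10 px) minus `M`. It surrounds the cell (clipped at image edges) and may
  overlap neighbouring cells; laminin scanning does not exclude neighbour
  pixels, since membrane signal between touching cells is genuinely shared.
- **Face points.** A `laminin_window_px` × `laminin_window_px` window
  (default 9×9, odd so a centre pixel exists) is evaluated at every position
  whose centre lies in the region. The window value is the mean laminin over
  the in-bounds window pixels — windows are clipped at the image edge (the
  mean divides by the in-bounds count) but are *not* clipped to the region.
  The argmax centre is the vascular point, the argmin the avascular point;
  exact ties resolve to the first position in row-major scan order, which
  makes the operation deterministic.
- **Line-scans.** From each face point a Bresenham line (8-connected,
  monotone in the dominant axis) is drawn to the cell centre, defined as the
  unweighted centroid of the mask pixels rounded to the nearest pixel. At
  each line coordinate inside the cell, the mean insulin over an even
  `insulin_window_px` × `insulin_window_px` window (default 10×10, anchored
  at offsets −5…+4 in both axes) intersected with the cell mask and the
  image is computed; the cell's face value is the maximum of these means.
  A line with no in-cell coordinate yields NaN; such cells are dropped
  listwise from statistics and counted in the log/manifest.
- **Size filter.** Watershed instances with area ≤ 490 px (a ~5 µm-radius
  cut in 512² resized planes; strict inequality, so 491 px survives and
  490 px does not) are excluded before analysis.
- **Statistics.** Paired two-tailed Student's t: d = vascular − avascular
  per cell, t = mean(d)/(sd(d)/√n) with the n−1 sample deviation, p from the
  t distribution with df = n−1. If every difference is exactly zero the
  statistic is undefined and flagged degenerate. Summaries report mean ± SEM
  (sd/√n) and also SD, since both conventions appear in practice and with
  cell-to-cell spreads this large they differ by an order of magnitude.
  Two planned tests (laminin, insulin); no multiplicity correction.

A manual-style cross-check (`manual_linescan`) rasterises a single line from
the vascular to the avascular point and averages insulin over the first
`round(depth_um / pixel_size_um)` in-cell pixels inward from each face
(default 2 µm ≈ 6 px at 0.3604 µm/px), flagging truncation when the depth
exceeds half the in-cell line. On noise-free synthetic cells its vascular
means correlate with the automated read-out at Pearson r ≈ 0.80; the
correlation is carried almost entirely by cell-to-cell brightness variation,
as both statistics are otherwise deterministic functions of geometry.

## Instance segmentation

Marker-controlled watershed: Euclidean distance transform of the semantic
mask, Gaussian-smoothed (σ default 2.0 px), local maxima at least
`min_marker_distance` apart (default 10 px ≈ half a typical resized cell
diameter) as markers, watershed of the negated smoothed distance restricted
to the mask. Markers are numbered in row-major order so equidistant floods
resolve deterministically; 4-connectivity throughout prevents
corner-touching cells from merging. Components holding a single marker come
out identical to their connected component, so disjoint cells are counted
exactly; on close-packed synthetic islets the aggregate count over 50
simulations is within ~2% of truth (slight under-segmentation where two
cells share one smoothed distance maximum).

## Semantic segmentation

The U-Net is implemented directly in NumPy (`_nn.py`: im2col convolutions,
ReLU, 2×2 max-pool, nearest-neighbour upsampling, Adam, logit-space BCE)
with a configurable depth (default 2 encoder levels) and base filter count
(default 8). That scale is intentional: the scientific content of the module
is the protocol — per-pixel binary cross-entropy, early stopping on
validation loss (patience 10, best weights restored, fractional mean
stopping epochs across folds), image-level K-fold partitioning with optional
transfer pretraining, and pooled-pixel confusion metrics per fold — not the
network's capacity. On synthetic planes, where cells are bright in the
insulin/nuclei channels, a 20-epoch CPU run on 32 planes of 128² reaches
held-out pixel accuracy ≈ 0.998 and IoU ≈ 0.99. Undefined precision/recall
(zero denominator) is reported as 0; binarisation threshold 0.5. Everything
is seeded and single-threaded, so training is bit-reproducible.

## The synthetic generator

`synthetic.generate_islet` emulates the statistical structure the analysis
assumes, not confocal optics:

- **Capillaries**: two or more random-walk centrelines (Gaussian direction
  jitter, σ = 0.25 rad/step; later walkers branch from the existing path so
  the network is connected), dilated to a half-width of 6 px (~4.3 µm
  vessels at the 0.3604 µm/px resized scale); occupies 2–15% of the plane.
- **Cells**: seeded a fraction of their radius (drawn from N(16, 3²) px,
  β cells ~10–13 µm across) away from the capillary wall, grown by watershed
  on a jittered distance-to-seed surface restricted to non-capillary pixels
  and the cell's own radius — irregular, close-packed, non-overlapping
  instances whose ground-truth contact point is the boundary pixel nearest
  the capillary. Cells that fail to reach the capillary wall are dropped;
  ≥90% of requested cells place under defaults.
- **Channels**: laminin = capillary mask at level 180; insulin =
  `base·f_c·(1 + (r−1)·g(p))` with base 100, per-cell brightness factor
  `f_c ~ N(1, 0.15²)` (real islets show large cell-to-cell insulin spread),
  and `g` the linear contact gradient; ~25 granule speckle discs per cell at
  +40; nuclei = one blurred disc per cell; additive Gaussian noise σ = 6 on
  all channels, clipped to 8 bits. All randomness flows from one seeded
  generator, so identical parameters give bit-identical islets.

What the generator does **not** model: point-spread-function blur, z-bleed
between planes, α/δ cells and other non-β tissue, membrane (syntaxin)
staining, laminin sheath sub-structure, uneven illumination. Passing tests
therefore demonstrate the correctness and internal consistency of the
measurement chain under known truth — not segmentation performance on real
confocal data, which depends on training data the package does not ship.

## Two structural limits of the read-out (measured, not hidden)

Two properties one might expect of the pipeline are *not* achievable under
this measurement definition, and the test suite states them at their nominal
thresholds so they fail visibly rather than being silently relaxed:

1. **The programmed enrichment ratio is compressed.** The avascular
   line-scan also ends at the cell centre, where the linear contact gradient
   is ≈ 0.5 for any convex cell (the centre sits about halfway along the
   maximal chord from the contact). Its maximum windowed mean is therefore
   at least `base·(1 + 0.5(r−1))`, while the vascular maximum is at most
   `base·r`, bounding the recoverable vascular/avascular mean ratio at
   r = 1.4 to ≤ 1.4/1.2 ≈ 1.17; measured ≈ 1.03–1.05 with default noise and
   speckle. The *direction* and *significance* of the effect are robust
   (paired p < 10⁻⁹ at n = 200; per-cell ordering holds for ~80% of clean
   cells), so the pipeline answers "is insulin vascular-enriched?" reliably
   while systematically understating the magnitude.
2. **The vascular point is not a contact-point estimator.** The 9×9 laminin
   window mean is translation-invariant along a locally straight capillary,
   so its argmax lies anywhere on a ~±17 px run along the vessel inside the
   boundary region, and at the tube centreline rather than at the cell
   boundary — median 9 px from the true contact, essentially never within
   5 px. It reliably identifies the vascular *side* of the cell (which is
   all the paired comparison needs), not the contact pixel.

## Numerical and design choices

- Coordinates are 0-based (row, col), origin top-left; masks are {0, 1}.
- Dilation is implemented as a Euclidean distance-transform threshold,
  exactly equivalent to a disc-footprint dilation and O(N) in image size.
- Windowed means use box-filter sums divided by in-bounds counts, matching a
  naive per-pixel loop to floating-point round-off.
- 3-D stacks keep the axial anisotropy (z_um/xy_um, ≈3.7 for the native
  0.0902/0.3362 µm confocal geometry) as TIFF metadata instead of resampling
  voxels; viewers apply the scale.
- Augmentation defaults (rotation ±90°, shear 0.15, shift ±10%, both flips,
  reflect padding; nearest-neighbour for masks, bilinear for intensities)
  are conventional generator settings; each output pair records one shared
  transform so image/mask alignment is exact by construction.
- Experiment sizes used by the acceptance script and tests (200 cells for
  enrichment recovery; 100 replicate 256²/20-cell simulations for the
  type-I rate; 50 simulations for instance counting; 32 planes of 128² for
  U-Net training) were chosen as the smallest runs that make the measured
  rates stable to well within the asserted margins.

## Known limitations

- The per-cell ratio compression above means `enrichment_ratio` should be
  read as a generative parameter, not as the value the read-out returns.
- The watershed has no split/merge correction; elongated cells with two
  distance maxima beyond `min_marker_distance` are split.
- The U-Net is single-channel-stack 2-D; no 3-D context across planes.
- The paired analysis pools cells across planes and islets (as the
  measurement design intends); no hierarchical per-donor modelling.
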