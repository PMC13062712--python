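# Methods

## Problem and scope

`seedpheno` quantifies seed-abortion phenotypes in photographs of
*Arabidopsis thaliana* seed populations dispersed on white paper. In a
triploid-block cross, seeds fall into three categories: **normal**
(plump, light brown), **partially collapsed** (misshapen, darker) and
**fully collapsed** (shrivelled, dark brown). The pipeline detects
every seed instance, summarises it as a fixed 38-value descriptor
record, and classifies it with a random forest. All stages are
exercised end-to-end on synthetic scenes with exact ground truth, so
the package is fully testable without any image downloads.

## Preprocessing and background normalization

Images are 8-bit RGB (JPEG/TIFF; 16-bit TIFF is linearly rescaled to
8 bit over the full dtype range, so 65535 maps to 255). Lighting is
corrected by a **global multiplicative background normalization**: the
background region is the bright class of an Otsu split of the blurred
luminance histogram (white paper is always brighter than seeds), the
per-channel background level is the median over that region, and each
channel is scaled by `255 / level` and clipped. The choice of a single
global factor per channel — rather than histogram matching or local
flat-fielding — keeps relative seed colour intact and is idempotent to
within one grey level. A constant (degenerate) image is passed through
with a flag.

Grayscale conversion uses the BT.601 luminance weights
(0.299 R + 0.587 G + 0.114 B, rounded). Gaussian smoothing uses
`sigma = 2.0` px by default (reflective boundaries); sigma is
config-exposed because the right value scales with the optical zoom —
it should stay well below the seed radius (seeds here are ~13–15 px in
radius at the default synthetic scale).

## Hybrid segmentation

Foreground is the dark class of an Otsu threshold of the blurred
luminance. Canny edges (hysteresis 50/150 on the 0–255 scale,
computed on the unsmoothed grey with the detector's own 1 px blur) are
subtracted to cut the thin bright seam between touching seeds; hole
filling then restores any cuts that do not reach the background, a 3×3
opening removes slivers, and components under `min_area = 100` px are
dropped as debris (logged, never silently "corrected"). Because edge
subtraction and opening shave roughly one pixel off every true
boundary, components are grown back inside the raw threshold mask with
`expand_labels` (distance 1.5); expansion stops at equidistance and the
contact band between different labels is kept clear, so separated
components can never re-merge.

Components are routed by a robust reference seed area `A_ref` — the
median area of compact components (solidity ≥ 0.90), falling back to
the median of all components. A component is a **cluster** iff its
area exceeds `1.6 · A_ref` or its solidity falls below 0.85; everything
else is a singleton seed (provenance `threshold`, quality 1.0). All
three routing constants are config-exposed; the 1.6/0.85 pair was
chosen so that a tangent pair of even the smallest phenotype usually
trips at least one of the two tests.

### Dense backends

Both backends honour one contract: returned masks lie ≥ 90% inside the
cluster, have area in `[0.3, 1.6] · A_ref`, and survive greedy
non-maximum suppression at IoU ≤ 0.3 ordered by quality; if the
surviving masks cover less than 80% of the cluster, the whole cluster
is returned as a single quality-0.2 mask.

The **watershed** backend computes the Euclidean distance transform of
the cluster mask, places markers at its local maxima with minimum
separation `0.8 · sqrt(A_ref / π)` and runs a marker-controlled
watershed; fragment quality is its solidity. Two refinements handle
hard geometry: (1) fragments still larger than `1.6 · A_ref` are
re-split recursively with the marker separation halved — only oversize
fragments are revisited, so single seeds are never over-split; and
(2) cluster regions the accepted fragments do not explain (typically a
side-by-side pair whose contact leaves no distance-transform neck) are
returned as additional quality-0.2 masks rather than discarded with the
whole split — the low quality flags them for review while keeping the
count honest.

The **SAM** backend adapts a promptable automatic mask generator
(points_per_side = 49, pred_iou_thresh = 0.86 by default) run on a
padded crop of the cluster, with quality = predicted IoU, filtered
through the same contract. It requires the `segment-anything` package
and model weights; if they are unavailable the backend raises a
backend-unavailable error — never a silent fallback — and the test
suite exercises the adapter through an injected generator instead.

Final masks are re-checked globally for pairwise IoU ≤ 0.3 and indexed
row-major by centroid (y, then x), which makes indices and masks
deterministic across runs. Contours are traced along pixel cracks
(half-integer corners) with a sharpest-right-turn rule at pinch points,
so rasterizing a contour reproduces its mask exactly.

## Descriptors

Each seed is an ordered record of 38 values (the canonical order is
`DESCRIPTOR_NAMES` and is embedded in every model bundle):

* **21 colour**: mean/std/median of R, G, B (on normalized pixels);
  mean/std of H, S, V (scikit-image scales, H in [0, 1]); mean/std/median
  of grey; mean L\*, a\*, b\*. Colour is computed on *normalized* RGB so
  values are comparable across lighting conditions.
* **9 shape**: area (px), perimeter (px), eccentricity, solidity,
  **overlap ratio**, circularity `4πA/P²` (capped at 1.1 for
  discretization slack), aspect ratio (major/minor of the fitted
  ellipse), extent, convexity (hull perimeter / perimeter).
* **5 texture**: grey-level co-occurrence contrast, dissimilarity,
  homogeneity, energy and correlation. Grey is quantized to 32 fixed
  bins (width 8); matrices are accumulated at distance 1 for
  0°/45°/90°/135°, restricted to pixel pairs both inside the mask
  (implemented by assigning out-of-mask pixels a sentinel level),
  symmetrized, normalized and averaged over angles. A zero-variance
  (constant) seed takes correlation = 0 by convention.
* **3 position**: centroid x, y and nearest-neighbour centroid
  distance (image diagonal when the image holds a single seed, flagged).

The ellipse fit is moment-based: the ellipse sharing the mask's
centroid and second central moments (semi-axes are twice the square
roots of the covariance eigenvalues). It is deterministic and safe on
degenerate masks (minor axis clamped to 0.5 px with a flag), unlike
algebraic contour least-squares. The **overlap ratio** is the IoU
between the mask and that ellipse rasterized at pixel centres — near 1
for plump seeds, visibly lower for collapsed ones; it is the shape cue
human annotators use most.

Per-seed extraction can run across threads; parallel and serial runs
produce identical values because each record depends only on its own
mask (the nearest-neighbour distance is filled in afterwards from final
centroids).

## Annotations

Manual labels are ImageJ multipoint exports: plain text rows of
`x y counter` (tab/comma/semicolon/whitespace separated, optional
header row, counter 0/1/2 = normal/partial/full). Points are matched
to masks by containment (boundary inclusive). Masks receiving
conflicting categories are excluded from training; points inside no
mask are reported as unmatched. Every input point is accounted for in
exactly one of these buckets — losses are visible, never silent.

## Classifier

A random forest with 100 trees, depth cap 7, minimum split 5,
bootstrap and out-of-bag scoring — fitted on a single stratified 70/30
split with `random_state = 42`. A grid search over
`n_estimators {100, 200, 500} × max_depth {5, 7, 10, None} ×
min_samples_split {2, 5, 10}` can be enabled (`grid=default_grid()`);
candidates are scored by accuracy on the held-out split, ties keeping
the earlier grid point, and the winner is refit on the training part.
By default no search runs and the stated final parameters are used
directly — the training-set-size analysis always uses this no-search
path so curves measure data volume, not hyperparameter luck.

Models are persisted as versioned bundles embedding the 38-name
descriptor order and class order; prediction refuses feature tables
whose header deviates, so a stale model fails loudly instead of
mis-predicting. Probabilities are forest vote fractions; ties at the
argmax resolve to the lower class code.

The **down-sampling harness** draws class-stratified random subsets of
a training pool (seed = base_seed + iteration), trains with the final
defaults, and scores on the full pool and an independent validation
set; the plateau is the smallest size whose mean validation accuracy is
within 0.001 (absolute) of the next larger size.

## Reporting

Batch prediction writes, per input directory: colour-annotated PNGs
(green = normal, orange = partial, red = full; contours and index
labels only, all other pixels untouched), a per-seed
`seed_parameters.csv` (ids, provenance, 38 descriptors, class,
probabilities, confidence; byte-identical across reruns), and a
per-image `seed_summary.xlsx` with a value-identical CSV twin
(spreadsheets for users, CSV for pipelines). Physical areas use
`area_mm² = area_px · (µm/px / 1000)²` when a calibration is supplied;
calibration is never inferred from burned-in scale bars.

Reproducibility of repeated imaging is `1 − CV` (CV = sample SD /
mean, ddof 1) of per-image counts per population and category;
categories averaging ≤ 10 seeds per image are flagged excluded because
the ratio is unstable at small counts.

## Synthetic scenes

The generator renders each seed as an ellipse whose radius is
modulated by random low-order sinusoids (total amplitude ≤
`radial_noise_amp`), filled with a per-seed colour offset plus
per-pixel Gaussian speckle. Default contrasts (relative to a 700 px
reference): normal — amplitude 0.04, RGB ≈ (181, 141, 96), area 1.0;
partial — 0.15, (135, 102, 70), 0.9; full — 0.35 with ≥ 5 harmonics,
(84, 58, 38), 0.65. **Partially collapsed seeds are rendered as a
severity continuum**: each draws a severity in ±0.7 and interpolates
its parameters toward the normal or fully-collapsed endpoint. This
mirrors the biology — partials genuinely share characteristics with
both neighbours — and is what makes them the hardest class for both
humans and the forest, rather than an artificially separable cluster.

Seeds are placed by rejection sampling: dispersed seeds keep ≥ 3 px
clearance; clustered seeds form touching chains placed by support-
function tangency (tightest zero-overlap spacing along a random
direction), honouring the acquisition rule that seeds may touch but
never stack. Backgrounds are near-white (245–255); `dark`/`bright`
lighting multiplies the final image by 0.7 / 1.2 (clipped). Everything
is deterministic given the scene's RNG seed.

What the generator does **not** emulate: specular highlights and
shadows, out-of-focus blur, silique debris and foreign objects,
within-seed colour gradients, and camera noise correlations. Passing
tests therefore demonstrate the pipeline's logic, determinism and
robustness to the modelled factors (touching, lighting gain, class
overlap) — not performance on real photographs, which depends on
acquisition quality and a model trained on real annotated images.

## Problem sizes and numerical choices

The test suite and acceptance script run scenes of 100–300 seeds at
~1200×1700 px (about 2 Mpx, the scale at which a 300-seed population
fits at under 12% coverage), 20 scenes for count recovery, 1500
pipeline-generated examples for classifier evaluation, 7 re-renders
for reproducibility and a [50, 100, 200, 400] × 5 down-sampling grid —
sizes chosen so the full suite completes comfortably on one CPU while
every stage is still exercised at realistic densities. Determinism is
enforced throughout: fixed RNG seeds, single-threaded forests,
centroid-ordered seed indices, and float reprs in CSV output.

## Known limitations

* Side-by-side elongated seeds whose contact leaves no background seam
  and no distance-transform neck cannot be split by the watershed
  backend; they surface as a single quality-0.2 mask (≤ ~1% of seeds in
  dense synthetic scenes).
* Hue statistics use plain (non-circular) means; adequate for brown
  seeds far from the hue wrap-around, biased for red-adjacent hues.
* The cluster-routing rule assumes a roughly unimodal seed-size
  distribution; mixtures of very different seed sizes would need the
  area factor retuned.
* The SAM backend is an adapter contract only; its quality depends
  entirely on the injected model and is not validated here.
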