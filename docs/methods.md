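# Methods

## The quantity being estimated

Amyloid-beta (Aβ) burden in immunostained brain sections is conventionally
rated on a four-level ordinal scale (none < sparse < moderate < frequent)
per deposit morphology — cored plaques, diffuse plaques, and cerebral
amyloid angiopathy (CAA). `plaquescope` implements a quantitative
replacement: a sliding-window tile classifier produces, for each slide and
morphology, a *confidence heatmap* — a probability raster at 1/stride of
slide resolution — and the heatmap is reduced to a scalar

    CNN score = (number of detected deposit blobs) / (region area in heatmap pixels)

Blobs are the connected components of the thresholded, morphologically
cleaned heatmap. The score is a density (blobs per heatmap pixel of
region); it is compared across slides grouped by ordinal rating, diagnosis
or NIA-Reagan level with ANOVA + Tukey HSD, t-tests, Kruskal–Wallis and
Spearman rank correlation.

## Pipeline stages and their conventions

**Color normalization.** Reinhard normalization in the Ruderman log-LMS
l-alpha-beta space: each channel is affinely mapped so its mean/std match a
reference image's. The reference statistics shipped as the default
(`preprocessing.DEFAULT_REFERENCE_STATS`) are those of a default synthetic
slide rendering; any RGB image can serve via `compute_lab_stats`. LMS
values are floored at 1e-6 before the log; outputs are clipped to the RGB
gamut, so normalization is exact only for in-gamut results (the
idempotence contract allows one quantization step).

**Tissue segmentation.** Inclusive thresholding in
lightness–chroma–hue (cylindrical CIELAB). Defaults (L ≤ 92, C ≥ 4)
separate stained tissue from near-white glass; thresholds are per-slide
configurable because staining varies.

**Tiling.** Row-major grid; the edge policy pads right/bottom with white
(white reads as background for both the segmenter and the classifier).
Tile count per axis is `floor((dim − tile)/stride) + 1` on the padded
image.

**Classifier.** Input 256×256×3; six 3×3 same-padding convolution blocks,
each followed by 2×2 max pooling (spatial 256 → 4); dense layers of 512
and 100 units; three *independent* sigmoid outputs, one per morphology —
a tile can contain several pathologies, so the heads are multilabel, not
softmax. Channel progression (8, 16, 32, 32, 32, 32), ReLU, He
initialization, Adam, binary cross-entropy. The network and its backward
pass are implemented directly on numpy arrays (im2col convolutions,
shift-and-matmul gradient accumulation); at the desk scale this package
targets — thousands of tiles, a few epochs, CPU — a full training run
takes minutes. Determinism is seeded; the contract is metric-level, not
bitwise across BLAS builds.

**Heatmap inference.** The classifier slides across the slide at a fixed
stride (default 16 px); heatmap pixel (i, j) holds the probabilities of
the window with top-left (i·stride, j·stride), so a 4096² slide yields a
241² heatmap. Windows with under 50% tissue coverage (integral-image
test) are skipped and left at zero.

**Scoring.** Per class: threshold the heatmap channel (default 0.9 for
all three classes — the thresholds are a config surface, calibrated per
deployment), then one iteration each of morphological opening and closing
with a 3×3 cross, then 8-connected component labeling. Score = component
count / region pixel area. When scoring a region (gray matter), the
region mask is applied to the heatmap *before* thresholding and labeling,
so boundary-straddling deposits are truncated and possibly split; the
area denominator is the region's heatmap-pixel count. Both numerator and
denominator live at heatmap resolution — whether the original analysis
divided by slide- or heatmap-resolution area is not documented, and the
ratio is only approximately invariant to that choice, so one convention
is fixed here.

**Gray-matter restriction.** Percent change = 100·(gm − wt)/wt per slide
and class; undefined (NaN) when the whole-tissue score is zero.

**Field-of-view (FOV) analysis.** Square windows of fixed physical area
slide across the heatmap. With defaults (251 heatmap px per side, 16 WSI
px per heatmap px, 0.5 µm per WSI px) a window spans 2.008 mm per side =
4.03 mm², emulating the ~4 mm² field of a 10× objective used in
conventional highest-density-region scoring. Window stride is in heatmap
pixels (default 16). Blobs are detected once globally and assigned to
windows by centroid membership (half-open extents), which prevents double
counting inside a window and makes blob counts over any non-overlapping
tiling sum exactly to the global count. The FOV score divides by tissue
pixels within the window; windows not fully inside the heatmap are
skipped so all windows have equal area. Top-n selection is greedy by
descending score with row-major tie-break, discarding windows that
overlap an already-selected one; greedy selection for n is a prefix of
the selection for any larger n, which the convergence analysis exploits.

**Cohort statistics.** Classical equal-variance one-way ANOVA (Welch is
available behind a flag) with Tukey HSD over all pairs, adjacency flagged
for ordered groupings; pooled-variance two-sided t-tests; tie-corrected
Kruskal–Wallis; Spearman with midrank ties (ordinal levels encoded
none=0…frequent=3, no/low=0…high=2). Significance stars at
0.05/0.01/0.001/0.0001. No correction is applied across families, only
Tukey within a family. Diagnosis groups: control; pure AD (no secondary
diagnosis); all AD; AD+TDP-43; AD+LBD with amygdala-predominant-only Lewy
body cases excluded from the LBD group; clinically-normal cases with AD
pathology at autopsy are excluded by default (toggleable). NIA-Reagan "no"
and "low" merge into one ordered group.

## The synthetic-data generator

The generator fabricates every input the pipeline consumes, with planted
ground truth, at two resolutions:

* **Heatmap-direct** (`generate_heatmap`): supra-threshold blobs (≥ 0.92)
  planted straight on the probability raster, plus a sub-threshold
  background murmur (uniform < 0.05) inside tissue. Used to test scoring,
  FOV and statistics without any classifier.
* **Slide rendering** (`generate_slide_image`): near-white background,
  bluish (hematoxylin-like) tissue, brown (DAB-like) deposits, Gaussian
  pixel noise. Used to test normalization, segmentation and the
  classifier loop.

Geometry: tissue is an inset rectangle; gray matter is its left band
(`gm_fraction` of tissue area, default 0.6). Deposits per class are
planted at `class_densities` (deposits per mm² of gray matter; defaults
12/8/4 for cored/diffuse/CAA, a CERAD-flavored scale), with
`white_matter_leak` of them placed outside gray matter. Placement samples
a random-offset lattice whose pitch exceeds the class footprint plus the
minimum gap, so deposits can neither merge under the default closing nor
straddle the gray-matter boundary — the guarantee behind exact count
recovery and partition conservation. Deposit footprints (cored: discs,
diffuse: irregular disc unions, CAA: rings) are pre-opened with the
default 3×3 cross and reduced to one component, so the scoring stage's
default clean-up provably preserves each planted deposit as exactly one
blob. An optional clustering control (`cluster_sigma_frac`) concentrates
deposits around several random patches, emulating the patchy spatial
statistics of real plaque fields.

Cohorts (`generate_cohort`) assign ordinal levels cyclically (balanced
groups) and realize per-slide densities as level density + truncated
Gaussian noise — the simplest controllable monotone-plus-noise structure.
Training tiles (`generate_training_tiles`) carry class-colored blobs plus
a small class-specific global tint, making class presence linearly
separable from color statistics; this is a sanity dataset for the
training loop, not a claim about real stain appearance.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: true plaque morphology and size distributions,
stain variability, fading, tears and artifacts, gray/white boundaries
with curvature, and classifier errors (the heatmap-direct route bypasses
inference entirely). Results on synthetic cohorts validate the *pipeline
mechanics* (geometry, counting, conservation, statistics), not biological
detection performance.

## Validation study designs

* **Rank-structure recovery** (`experiments.cohort_rank_experiment`):
  40-slide cohorts, four levels, cored-plaque densities 0/4/12/25 per
  mm², noise at 10% of the mean inter-level gap, slides of 8192 px (497²
  heatmaps — a desk-scale stand-in for gigapixel sections chosen so that
  sparse slides still carry tens of deposits), deposits clustered in 3–8
  random patches. Whole-tissue score vs level Spearman is ≈ 0.97 (median
  over seeds); the single densest scaled-down FOV (48 heatmap px windows,
  stride 8) correlates worse than the mean of the top 3–15 non-overlapping
  FOVs, which approach the whole-tissue correlation from below — the
  qualitative signature that whole-region scores out-rank densest-field
  scores.
* **Gray-matter shift** (`experiments.gray_matter_experiment`): with 15%
  of deposits leaked into white matter and gray matter at 60% of tissue,
  restricting scoring to gray matter raises cored/diffuse/CAA scores by a
  common geometric factor ≈ (1 − leak)/gm_fraction; the experiment
  reports the realized per-class average percent change.

## Numerical choices and degenerate inputs

Zero-iteration morphology is the identity (scipy's `iterations=0` would
iterate to convergence, so it is special-cased). Empty region masks are
an error (score undefined); zero whole-tissue score makes percent change
NaN. Constant images are rejected by `compute_lab_stats` (zero-variance
channel). Degenerate t-test inputs (both samples constant, equal means)
return (0, 1); all-tied Kruskal–Wallis and constant-input Spearman return
NaN. AUROC for a single-outcome class is NaN. Tie-breaks: greedy FOV
selection by (−score, row, col); blob labels follow scipy's scan order.

## Known limitations

The classifier is desk-scale: no augmentation, no GPU, no attempt to
reproduce any published weights or institutional ROC values. At very
short training schedules (a couple of epochs) one of the three sigmoid
heads occasionally lags behind the others for an unlucky weight
initialization; an extra epoch absorbs this, and the validation
experiments size their schedules accordingly. The
synthetic separability experiment demonstrates that the train→infer loop
is wired correctly, not that the architecture detects real pathology.
Cohort statistics assume one score per slide; spatial within-slide
distributions beyond the FOV analysis are out of scope, as are blob
morphology classification and size distributions.
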