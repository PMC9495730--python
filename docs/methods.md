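# Methods

This note documents the models, conventions and design choices behind
`renalmil`, in the order the pipeline runs them.

## Stain normalization

Color transfer uses the Reinhard opponent-space pathway: RGB in [0,1] →
linear LMS through the published 3×3 matrix, elementwise log₁₀ with a floor
of 10⁻⁶ (so black pixels stay finite), then the fixed diagonalizing matrix
to ℓαβ. The forward matrices are pinned verbatim as module constants; the
inverses are computed from them with `numpy.linalg.inv` rather than copied
from rounded published tables, which makes the RGB→ℓαβ→RGB round trip exact
to float precision (tests assert ≤1 intensity level at ≥99 % of pixels).
One consequence of pinning the published constants: their rows do not sum
exactly equally, so an achromatic pixel maps to |α|,|β| ≈ 10⁻³ rather than
exactly 0. This is a property of the published matrices, not an
implementation error.

Normalization proper is per-channel histogram specification in ℓαβ: a
reference profile stores each channel's quantile function on a probability
grid (default 1024 bins, linear interpolation), and each source channel
value is replaced by the reference quantile at the source's empirical CDF
(mid-rank convention for ties, so self-normalization is near-identity).
The map is monotone within each channel — within-slide ordering is
preserved up to ties. All pixels participate; there is no tissue masking at
this stage, because background handling belongs to the tiling stage. A
mean/variance-only transfer (`method="reinhard"`) is available behind the
same interface; the reference moments are recovered from the stored
quantile function by integrating the inverse CDF.

A deliberate consequence of histogram specification worth stating: it
forces every slide's *marginal* color distribution onto the reference's, so
any information carried purely by a slide's global color composition is
removed. Class evidence must live in spatial structure (and in joint /
local color relationships), which is exactly the regime the synthetic
fixtures are designed to emulate.

## Tiling

Coordinates are 0-based `(row, col)` with half-open extents. Training
patches lie on a full-fit sliding grid: offsets {0, s, 2s, …} per axis,
per-axis count `floor((dim − window)/stride) + 1`, stride 50 by default; no
padding anywhere. A pixel is background iff HSV saturation < 0.08 and value
> 0.85 (near-white, unsaturated); a tile is discarded when its background
fraction *exceeds* 0.25 (strict reading of "more than 25 %" — a tile at
exactly 25 % is kept). Patches at 200 and 100 px come from their own
stride-50 grids rather than being cropped out of 400-px tiles: independent
grids maximize coverage, and the choice is configurable.

Concentric test sets anchor a small s-patch on a grid with stride s
(non-overlapping by default; overlap would add cost without changing the
fusion contract). The "center" of an even-sized patch is defined as
`top_left + size/2` — the pixel just below/right of the geometric center —
applied identically at all scales, which makes the 2s-parent offset
(−s/2, −s/2) and the 4s-parent offset (−3s/2, −3s/2) exactly integral. A
set is emitted only when all three patches lie fully inside the image
(boundary sets are dropped, never padded: padding would fabricate tissue
context); on an 800×800 image with s = 100 this leaves small-patch anchors
in {200, 300, 400, 500} per axis, i.e. 16 sets. The background filter is
applied to the small patch only — it decides whether the *center* of the
set is informative tissue.

## Classifier bank

One classifier per scale, no parameter sharing. The shipped architecture
(`small_resnet`) is a compact residual network written in NumPy: a
conv–BN–ReLU stem, an identity residual block, 2×2 average pooling, a
widening conv–BN–ReLU, a second residual block, pooling, global average
pooling and a dense softmax head (width 12 ≈ 20k parameters). Forward,
backward and the optimizers (Adam default; SGD-with-momentum and RMSprop
selectable) are implemented in `renalmil.nn` and verified against numeric
gradients. Everything is float64 and seeded, so training is reproducible
bit-for-bit given (seed, config, data) — the test suite asserts exactly
that, and checkpoints (npz weights + JSON sidecar with scale, class order,
architecture, input size, seed) restore identical predictions.

Two sizing choices keep CPU training honest without changing the method:

* **Input resolution.** Each scale model block-averages its native patch to
  a small network input — 25×25 for the 100- and 200-px scales, 50×50 for
  the 400-px scale (at most 8× downsampling). The scale distinction the
  method relies on is the *field of view* (100 vs 200 vs 400 px of tissue
  context per input), which is preserved; only the microns-per-input-pixel
  differ. The 400-px scale gets the larger input because it has ~4× fewer
  patches, keeping per-scale compute balanced.
* **Batch-norm momentum 0.3.** Desk-scale epochs are 7–30 mini-batches; with
  the conventional 0.1 momentum the inference-time running moments lag the
  batch moments by several epochs, making the monitored validation accuracy
  misreport the network and misfire the schedulers below.

Training regimen: mini-batch 64, categorical cross-entropy, initial learning
rate 10⁻³, at most 10 epochs. A stratified 10 % validation split (per patch,
seeded; never smaller than the class count) is held out to monitor
validation accuracy. The learning rate is multiplied by 0.1 after 2 epochs
without improvement; training stops after 6 epochs without improvement
(patience chosen so the decayed rate gets a chance to act before training is
abandoned), and the best-validation parameters are restored. A per-slide
validation split would be less leaky than the per-patch split; with ≤3
slides per class it is not statistically meaningful, so the per-patch
convention is used and noted here.

Weak labels: each patch inherits its slide's class (bag-level supervision).
No data augmentation and no pretrained weights are used.

## Decision fusion and aggregation

The per-patch rule is implemented twice: the published counter form (a
Boyer–Moore majority scan over the three votes followed by a membership
check against the first two votes) and the brute-force contract ("the label
occurring ≥2 times, else discard"). The suite proves them equal on all 4³
ordered triples — and that with two classes a discard is unreachable
(pigeonhole). The membership check against only the first two votes is
sufficient because a label occurring twice among three votes must occupy
one of the first two positions.

Slide aggregation majority-votes the non-discarded outcomes; fractions are
reported over non-discarded patches. Ties are broken by the higher mean
predicted probability over the tied class's supporting patches (falling
back to class order), always setting a tie flag. A slide whose every patch
was discarded is labeled `INDETERMINATE` rather than raising — one
degenerate slide must not abort a batch run — and such predictions score as
a miss for the actual class and are reported separately.

## Evaluation

Confusion matrices are actual-by-row, predicted-by-column. Per-class
metrics are one-vs-rest: accuracy (TP+TN)/N, sensitivity TP/(TP+FN),
specificity TN/(TN+FP), in percent. Per-class "accuracy" as one-vs-rest is
an interpretation — it is the only standard reading under which one class
can score 100 while others do not. A class with no positives in a fold has
undefined sensitivity: it is flagged and excluded from macro summaries.
Macro summaries are mean ± *sample* SD (n−1); display rounding is half-up
to one decimal (two for fold means), with raw values retained. These
conventions are pinned by tests that reproduce published summary rows from
their per-class values.

Cross-validation: stratified k-fold over slides (falling back to plain
k-fold when a class has fewer slides than folds) and LOSO, one fold per
subject, with a test asserting no subject ever appears on both sides of a
fold. Discarded patches are excluded from patch-level metrics (only fused,
class-bearing patches are scored); single-scale accuracies are computed
over all sets, since no discard mechanism exists for a lone classifier.

## Synthetic fixtures

The generator emulates the *contract-relevant* features of slide images:
near-white background regions (a low-frequency Gaussian random field
thresholded at the background fraction, default 0.30 — low-frequency so
that 400-px windows mostly fall in contiguous tissue, as on real slides),
a saturated tissue region, and seeded, hash-stable rendering (per-slide
streams spawned from the dataset seed).

Class identity is deliberately carried by structure, not palette: all four
classes share one H&E-like color pair and one blob-area budget (0.55 of
tissue area), so per-slide normalization maps are near-identical across
slides and anything the classifiers learn must transfer. The structure
ladder: blob diameters 20 (ccRCC), 44 (ccpRCC), 100 (parenchyma), 260 (fat)
px with SDs 2/4/10/24 — pairwise means separated by at least twice either
SD. ccpRCC additionally carries a fine dark speckle (10-px dots, 12 % of
tissue area) that only small fields of view resolve; fat's blobs are pale
vacuole-like regions (as adipose tissue is) whose full extent only the
400-px context contains, and whose light-against-base contrast polarity is
preserved by any monotone per-channel map. A `hard_spec` variant with
barely-separated diameters and near-identical palettes exercises the
discard and indeterminate paths. Global stain shifts
(per-channel multiplicative/additive) produce the normalization test pairs.

What the fixtures do *not* emulate: nuclei morphology, staining optics,
pyramidal WSI resolution levels, scanner artifacts, or intra-class
biological heterogeneity. Passing on fixtures demonstrates that the
geometry, filtering, weak-label training, fusion and scoring machinery is
correct and that the multiscale design does what it claims under controlled
conditions — not that any particular accuracy transfers to clinical data.

## Problem sizes and defaults

The default study is 12 slides (3 per class) of 800×800 px with 2-fold
cross-validation — one subject per slide by default (`slides_per_subject`
groups slides for LOSO exercises). At these sizes a full run (normalize,
tile, train three networks per fold, predict, fuse, score) takes a few
minutes on one CPU. The training window/stride (400/50), discard threshold
(0.25), scale set {400, 200, 100}, batch size, epochs, learning-rate
schedule and optimizer defaults are the method's stated operating point;
the network width, input resolutions and slide counts are the package's
desk-scale choices, selected so that the framework's properties are
exercised end to end.

## Known limitations

* The CNN is a compact residual network, not ResNet-50; the framework is
  architecture-agnostic (any scale-indexed classifier with the same
  interface slots in), but capacity-bound conclusions do not transfer.
* Histogram specification assumes the reference slide is representative;
  reference choice is left to the user (default: first manifest slide).
* Inputs are flat rasters (PNG/TIFF); pyramidal WSI formats are out of
  scope.
* Patch-level validation splitting slightly overestimates validation
  accuracy under weak labels (see above).
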