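# Methods

This note documents the models, conventions and numerical choices behind
`cystseg`, in the order data flows through the pipeline.

## Data model and conventions

Images are RGB uint8 arrays indexed (row, col), 0-based, origin top-left.
Binary masks are plain boolean arrays of the image shape; connected
components use 8-connectivity by default (annotated cysts are blobs, and a
diagonal join should not split one cyst into two), configurable to
4-connectivity everywhere it matters. Mask files are single-channel PNGs
with 0 = background and 255 = cyst. Catalogs are CSVs with columns
`image_id, experiment_id, treatment_id, tubule_id, z_index, image_path,
annotation_path`; a tubule is globally identified by the triple
(experiment, treatment, tubule), and z-stack images of the same tubule are
treated as independent images — the metrics make no attempt at volumetric
fusion.

**Rasterization.** Labelme polygons are rasterized with the pixel-center
rule: a pixel is foreground iff its center (col + 0.5, row + 0.5) is
inside a polygon, decided by an even-odd crossing test whose edges are
half-open in y, i.e. a consistent top-left fill convention for centers
exactly on an edge. Overlapping polygons union; polygons are filled
without interior holes. Tests compare this against an independent
per-pixel point-in-polygon oracle (shapely).

## Synthetic scenes

The generator emulates the visual structure an annotator relies on: a red
tissue band with a mild sinusoidal axis (the tubule wall), blue point
nuclei scattered in tissue and densified in a ring hugging each cyst rim,
cyst lumens dark in both red and blue, and a green channel of pure
uniform noise. Cysts are mildly rotated ellipses (aspect ratio 1–1.8),
pairwise disjoint with an 8 px margin.

Defaults follow the statistics of real engineered-tubule datasets: cyst
areas log-normal with median 78 µm², clipped to [30, 2000] µm²
(σ_log = 0.85, so the long upper tail reaches the clip only rarely);
cysts per image Poisson with mean 4 truncated at 12; image scale
0.5 µm/pixel, a typical confocal 20× scale chosen so the µm² targets map
to convenient pixel areas (median cyst ≈ 312 px). The ground-truth mask
is the rasterization of dense 64-gon approximations of the ellipses, so
synthetic data flows byte-for-byte through the same readers as real data
(image PNG + mask PNG + Labelme JSON + catalog CSV).

What the generator does **not** emulate: point-spread blur, z-bleed,
uneven illumination, real nuclei morphology, touching cysts, annotation
noise. Passing tests therefore demonstrate the correctness of the
pipeline's logic and the learnability of the synthetic task, not
microscope-grade segmentation performance.

**Perturber.** To test the object-level metrics with known answers, the
perturber corrupts a ground-truth mask while logging every action: drop a
component, split it with a 2 px background cut through its centroid (both
fragments still overlap the original cyst — the classic "overcount"),
erode/dilate its boundary by a jitter radius, and add small spurious
blobs (area 20–130 px, i.e. predominantly the smallest size zone,
mirroring the observation that wrong predictions are usually very small)
placed at least 12 px away from everything else so that moderate closing
cannot bridge them. Rates are applied as exact rounded fractions of the
component count rather than i.i.d. coin flips, which makes fixtures like
"split 1 of 3, add 2 blobs" deterministic in count while random in
selection.

## Preprocessing

`remove_green` zeroes the green channel and keeps three channels, so
3-channel pretrained backbones remain usable. Augmentation (training time
only; evaluation uses muting + normalization alone) applies horizontal
flip (p = 0.5), a ±90° right-angle rotation (p = 0.5) — right angles
because they are lossless and need no interpolation or border policy —
multiplicative brightness and contrast with factor in [0.8, 1.2] (p = 1),
gamma in [0.8, 1.2] (p = 0.5), CLAHE (p = 0.5) and normalization to
reference per-channel statistics (ImageNet mean/std by default, held in
config rather than hard-coded). The brightness/contrast "limit 0.2" is
interpreted multiplicatively; this is a documented convention visible in
the config. CLAHE is applied per channel on an 8×8 tile grid; its clip
limit is stated on the OpenCV scale (4.0) and divided by the 256
histogram bins to obtain scikit-image's normalized clip limit. Geometric
transforms are applied jointly to image and mask; photometric transforms
never touch the mask, which stays strictly boolean.

## Segmentation

A backend is any mapping from a preprocessed image to a per-pixel
probability map of the same height/width with values in [0, 1]. Maps are
binarized with a strict `p > 0.5` comparison (ties at the threshold fall
to background; tie handling is a documented choice).

The reference net is a miniature of the U-Net family: three resolution
levels, two 3×3 convolutions + instance normalization + ReLU per level,
2×2 max pooling, nearest-neighbour upsampling with skip concatenation,
and a 1×1 output head whose bias starts at −2 (near the background
prior), ≈ 0.12 M parameters at the default width of 16 channels. It is
implemented directly on numpy (channels-last; each k×k convolution is
computed as k² shifted 1×1 GEMMs), with hand-written backward passes that
are verified against numerical gradients in the test suite. Instance
normalization was chosen over batch statistics because it is
deterministic at inference and keeps single-CPU training reproducible.

Training recipe (fixed configuration): binary cross-entropy on logits,
Adam (β₁ = 0.9, β₂ = 0.999) at learning rate 10⁻⁴, batch size 8, cosine
annealing with warm restarts (T₀ = 10, T_mult = 2, η_min = 0; the rate
restarts at epoch boundaries 10 and 30), early stopping when validation
pixel-wise IoU has not strictly increased for 10 epochs (no minimum
delta), at most 100 epochs, returning the best-validation-epoch weights.
Validation IoU is accumulated over the whole validation set (summed
TP/FP/FN), not averaged per image; a validation split without any cyst
pixel is rejected up front because the stopping criterion would be
undefined. ImageNet pretraining is out of scope for the reference net;
training from random initialization on synthetic scenes is the testable
stand-in. On 64 synthetic 128×128 scenes this reaches validation IoU
≈ 0.9 within 30 epochs in under 10 minutes on one CPU core.

## Postprocessing

Hole filling converts every background component not connected to the
image border into foreground (cysts contain no holes); it never shrinks
foreground and is idempotent. Opening/closing use a circular structuring
element: the set of integer offsets within Euclidean distance (k − 1)/2
of the center, where the expert-facing parameter k is the **diameter**
(k = 1 is the identity, k = 3 the 4-connected cross; even k falls between
the neighbouring odd discs). Operations are computed on a canvas padded
with background and cropped back — the infinite-background convention —
so closing is extensive and opening anti-extensive everywhere, including
at image borders; both are idempotent and monotone, and the suite checks
exact agreement with a brute-force sliding-window min/max filter. The
pipeline order is hole filling first, then the optional morphology.
Choosing the operation and k is left to the domain expert; per-region
adaptive postprocessing is out of scope.

## Object matching and metrics

Pixel metrics come from TP/FP/FN counted over all pixels. For object
metrics, predicted and ground-truth components are matched one-to-one:
all component pairs satisfying the detection rule (≥ 1 shared pixel by
default; optionally pairwise IoU > τ) are sorted by descending pairwise
pixel IoU — ties broken by larger intersection, then lower component ids,
making the pairing deterministic — and accepted greedily. Matched pairs
are DT; leftover ground-truth components MS; leftover predictions WR.
This reproduces the canonical multi-overlap resolutions (one cyst hit by
two predictions → 1 DT + 1 WR; one prediction spanning two cysts → 1 DT +
1 MS), and on overlap graphs that are unions of stars — the dominant real
case — greedy attains the maximum possible DT, which the suite verifies
against exhaustive enumeration. Metrics with zero denominators are
reported as NaN and excluded from aggregation, never coerced to 0 or 1.

Cyst areas are converted to µm² via the configured scale and assigned to
size zones by left-closed/right-open intervals on the boundary list
(default 34.7 / 53.3 / 78.7 / 120.9 / 207.5 µm², six zones; an area of
exactly 34.7 µm² falls in zone 2). Equal-cardinality boundaries for a new
area sample are the k/n quantiles; collapsed boundaries from tied areas
are flagged with a warning. In zone attribution, DT and MS cysts are
placed by their ground-truth area and WR cysts by their predicted area
(a wrong prediction has no ground-truth counterpart); per-zone counts sum
to the global counts by construction.

## Cross-validation and aggregation

Images from the same tubule are strongly correlated, so the tubule is the
cross-validation unit: LOTO builds one fold per tubule, testing on all of
its images; the remaining tubules are split 80/20 into train/validation
**at tubule level** (the conservative reading of an ambiguous protocol;
validation count = ceil(0.2 · n), at least 1). Folds are reproducible
under a seed and invariant to catalog row order.

Within a group (tubule, treatment, experiment, zone) confusion counts are
summed and metrics recomputed from the sums (micro), which prevents
images with one tiny cyst from dominating; across groups the report is
the mean with a 95% normal-approximation confidence half-width
(1.96 · sd/√n over groups where the metric is defined) — a convention of
this package, stated as such rather than as a reproduction of any
particular published interval. Treatment reports include the max−min
spread per metric, the robustness check for treatment invariance.

## Problem sizes used in the checks

The automated checks run at desk scale by design: metric identities on
1000 random 32×32 mask pairs; morphology oracle agreement on 200 random
64×64 masks for k ∈ {3, 5, 7}; matching optimality on ~120 star
instances with ≤ 6 components per side; the learning check on 64 training
/ 8 validation / 6 held-out 128×128 scenes with the training cap at 30
epochs. The acceptance script mirrors these sizes.

## Known limitations

* The reference net is a demonstration-scale stand-in; published
  large-scale architectures plug in through the backend contract but are
  not re-implemented here.
* Synthetic scenes are easier than microscope data (see above); absolute
  metric values on them do not transfer to real tubules.
* Greedy matching is optimal on star overlap graphs but can in principle
  lose a match on overlap graphs containing paths/cycles of length ≥ 4;
  such configurations are rare for blob-like objects.
* Multi-class labels, volumetric fusion and proprietary microscope
  formats are unsupported.
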