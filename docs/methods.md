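# Methods

This note documents the models, conventions and design choices behind
`elastoselect`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, with which
defaults, and what the synthetic validation does and does not demonstrate.

## Problem setting

EBUS strain elastography encodes relative tissue stiffness as a color
overlay (yellow/red → softest, green → soft, blue → stiff). The clinical
quantity of interest is whether an intrathoracic lymph node is benign or
malignant; stiffer (bluer) nodes are more likely malignant. Both the
qualitative 1–5 grading and the quantitative metrics are computed on a
*single representative image* chosen from a ~20-second recording, so the
choice of frame is a first-order source of variance. The package's core
is an unsupervised selector that makes that choice reproducibly.

## Quality gating

Two per-frame gates, both computed on the full frame (selection precedes
any ROI delineation):

* **Colored-pixel proportion** `p = #{pixels: S ≥ s_min} / #pixels`, with
  S the HSV saturation on the 0–255 scale. An elastogram overlay is
  chromatic; a frame where the overlay dropped out is nearly achromatic
  and fails this gate. Achromatic pixels (R=G=B) have S=0 and never count.
* **Relative intensity** `r = mean V(frame) / median_f mean V(f)` with V
  the HSV value channel. The median (not mean) normalizer keeps a handful
  of dark dropout frames from dragging the reference down. Over- and
  under-exposed frames fall outside `[i_lo, i_hi]`.

A frame qualifies iff `p ≥ p_min` and `i_lo ≤ r ≤ i_hi`; all comparisons
are closed. Defaults: `s_min=40`, `p_min=0.15`, `i_lo=0.6`, `i_hi=1.4`.
The thresholds behind the published pipeline are not public, so these are
package defaults chosen to be permissive for genuine overlays and strict
for dropouts; every correctness test exercises the *rule*, not the
constants, and all are configurable.

**Thinning.** Adjacent qualified frames are near-duplicates (10 fps vs.
sub-hertz physiological motion). A greedy left-to-right walk keeps a
qualified frame and drops the next `gap` (default 2) qualified frames
within that distance, repeating. This interpretation — keep one, skip the
following two — reduces the kept set by about a factor 3 and matches the
stated purpose of avoiding an overwhelming number of near-identical
candidates; a symmetric ±1 removal around kept frames would reduce by at
most a factor ~2 and is not what is implemented.

## Features

Each kept frame is summarized by the joint **8×8×8 RGB histogram**:
channel value v falls into bin `v // 32`, flat index `64·bR + 8·bG + bB`,
counts normalized to sum 1. 512 bins factorize naturally as 8³ over a
*color* distribution; the histogram is deliberately invariant to spatial
layout and resolution. Normalization makes frames comparable across
recordings; the raw-count alternative would conflate resolution with
content. A mask-restricted variant exists (`roi=` argument) but is off by
default, since masks do not exist at selection time.

**PCA.** Fitted on training histograms only (scikit-learn, full SVD);
validation/test features are transformed with the frozen model. The
retained dimension `d` is the smallest whose cumulative explained-variance
ratio reaches `variance_target` (default 0.99) — a data-dependent quantity
(9 on the default synthetic cohort; ~40 is typical for clinical material).
Numerically-zero trailing components are stripped, and each component's
sign is fixed so its largest-magnitude entry is positive, making
serialized models reproducible bit-for-bit. Distances downstream are
Euclidean in the reduced space; at `variance_target=1` on full-rank data
the projection is an isometry (checked in tests to 1e-8).

## Pattern clustering and selection

**Training.** k-means (Lloyd, k-means++ seeding, best of `n_init=10`
restarts, fixed seed) on the reduced training features. K is a
hyper-parameter from {32, 64, 128} (default 64); `tune_hyperparameters`
grid-searches K × {run-once, run-twice} against a caller-supplied
validation scoring callback, because "validation performance" is
application-defined (e.g. diagnostic accuracy of a quantitative metric on
the selected images). Ties prefer smaller K, then run-once.

**Update-and-predict.** A finite training set under-covers acquisition
conditions, so test-time assignment with stale centers can mis-allocate
frames. The run-twice strategy: (1) assign test frames with trained
centers; (2) refresh the centers with Lloyd iterations to convergence
(max center movement ≤ 1e-6, cap 300 iterations, empty clusters re-seeded
to the farthest point, within-cluster sum of squares asserted
non-increasing every iteration) over the **pooled training+test**
features, initialized at the trained centers; (3) re-assign test frames.
No labels are consumed. Pooling the training features anchors the updated
model to the training distribution so it cannot forget it; a test-only
update (`pool_training=False`) is available for the aggressive-adaptation
alternative.

**Selection.** Per lesion (both videos pooled), the pattern owning the
most frames is the representative pattern; its `n_representatives=3`
members nearest the center are the representative images. All tie-breaks
are deterministic and documented: nearest-center ties → lower pattern id;
majority ties → smaller mean distance, then lower pattern id; distance
ties → lower frame index. A pattern owning fewer than 3 frames yields a
*short* selection (flagged, not an error), since pattern-poor videos occur
in practice.

## Quantitative metrics

Computed over an expert-drawn binary ROI:

* **SAR** = blue-classified pixels / all ROI pixels. Pixel classification
  uses hue windows on the 0–255 circle — red [0, 21] ∪ [234, 255], yellow
  (21, 64], green (64, 128], blue (128, 184] — centered on the canonical
  hues (red 0, yellow ~43, green 85, blue 170), with a chroma gate
  (saturation < 40 or value < 32 → unclassified). Window edges are
  configurable; the registered clinical program's exact thresholds are
  not disclosed, and all correctness fixtures place pixels well inside
  windows.
* **B/G, B/R, G/R** = ratios of summed 8-bit channel intensities over the
  ROI. Zero-sum denominators flag the ratio undefined (`None`), never
  infinity. A pixel-count-ratio variant of B/G is not the default because
  the channel-intensity reading matches the RGB-channel framing of the
  metric.
* **Mean hue** on the 0–255 full-range scale (achromatic pixels contribute
  hue 0, a documented convention). The full-range scale is the one
  consistent with published hue cut-offs near 134, which exceed a 0–180
  half-range.
* **Mean gray** = BT.601 luma `0.299R + 0.587G + 0.114B` on [0, 255]; a
  plain channel-average variant would differ only by fixed weights and is
  not exposed.

Class counts partition the ROI exactly; all metrics are invariant to pixel
permutation within the ROI.

## Statistical evaluation

Malignant is the positive class throughout. Grading scores dichotomize
1–3 → benign, 4–5 → malignant. Diagnostics follow the standard formulas
(Sen = TP/(TP+FN) etc.); undefined metrics (empty denominators) are
flagged `None`, and reported percentages round half away from zero to two
decimals, the convention of clinical tables. AUC is the Mann–Whitney
statistic over n⁺·n⁻ with ties counted ½ (computed by midranks); the ROC
direction is chosen so AUC ≥ 0.5. The operating cut-off maximizes Youden's
J = Sen + Spe − 1 over midpoints between adjacent distinct values (ties →
smaller cut-off); a max-accuracy criterion is selectable. The coefficient
of variation uses the **sample** SD (n−1) over the mean of a lesion's
three repeated values (the sample/population choice is not standardized in
the literature; sample SD is the conservative default, flagged undefined
at mean 0). Paired *t*, Friedman (tie-corrected, k=3) and Wilcoxon
signed-rank (zeros dropped; exact null for ≤ 25 untied pairs, tie-corrected
normal approximation beyond) wrap scipy with explicit degenerate-input
flags. No multiple-testing correction is applied; α = 0.05 two-sided.

## Synthetic data

The generator emulates the *structure* of elastography recordings, not
their physics. Per lesion: an elliptical ROI (~36% of a 128×128 frame) on
a dark achromatic background; 2 videos × 200 frames (20 s at 10 fps);
patterns are exact integer compositions of canonical colors (hue 170 blue
/ 85 green / 43 yellow / 8 red at saturation 220, value 230) painted over
a seeded permutation of ROI pixels. Benign dominant composition ≈ 15%
blue / 60% green / 25% yellow; malignant ≈ 55% blue / 30% green / 15%
yellow; 3 distractor patterns per lesion drawn from a 5-entry library,
all with per-lesion composition jitter (±0.04). Effect sizes (benign SAR
≈ 0.15 vs malignant ≈ 0.55) are the generator's own documented choice:
strong enough for reliable recovery experiments, not paper-derived.
Defaults: 60% of qualified frames from the dominant pattern, 15% of all
frames unqualified (alternating overlay-dropout/underexposure), per-frame
global hue jitter ±3 and per-pixel channel noise SD 5 inside the ROI;
background speckle is achromatic (identical noise on R, G, B), as in
B-mode imaging — and necessarily so, since independent channel noise on
dark pixels would register as high HSV saturation.

Because the histogram feature is spatially invariant, a pattern's feature
location is determined by its composition; jitter and noise give each
pattern a small within-cluster radius, and distinct compositions sit many
radii apart. The **test shift** (`test_shift`, default 0.6 when enabled)
interpolates a test lesion's dominant composition 60% of the way toward
its first distractor. This places the shifted dominant past the Voronoi
midpoint of the stale training centers — its frames are captured by the
distractor's cluster, whose own frames sit nearer the center, so
stale-center selection returns distractor frames. The update step
relocates centers onto the shifted mass and recovery returns. A
displacement expressed literally in "within-cluster radii" would be far
too small to cross any stale cluster boundary under the pattern
separations used here; the interpolation formulation produces the
phenomenon the shift is meant to model (acquisition drift between
training and deployment).

Every generated lesion self-checks at creation: the noiseless dominant
field is re-measured through the quant classifier and must reproduce the
planted class counts exactly. `generate_quant_fixture` builds
exact-composition images from pure canonical colors (e.g. (0,0,255),
hue exactly 170) whose expected metrics are computed by independent
closed-form arithmetic.

**What passing synthetic tests shows — and does not.** They validate the
machinery: gating matches planted qualified/unqualified truth, selection
recovers planted dominant patterns (24/24 lesions at the default
conditions; ≥22/24 after a shifted test split when the update step is
on), and SAR separates the generated classes (AUC 1.0 at n=24). They do
not demonstrate clinical performance: real elastograms have speckle
texture, probe-pressure drift, anatomical context and overlapping class
distributions that the generator deliberately omits, and real AUCs are
substantially below 1.

## Problem sizes and runtime conventions

The default experiment cohort is 24 lesions × 400 frames at 128×128 —
large enough that the training split (~2,200 kept histograms) supports
K=64 clustering, small enough for interactive iteration. Unit tests use
reduced cohorts (6–8 lesions, 30–40 frames, 64×64). The exhaustive
k-means oracle enumerates all Kⁿ assignments and is run at n ≤ 12, K ≤ 3.

## Known limitations

* Hue-window and quality thresholds are package defaults, not clinically
  validated constants; deployments should calibrate them per device.
* Video-container input depends on the imageio plugins present; frame
  directories are the canonical, always-supported input.
* The selector assumes the dominant *color* pattern is representative;
  lesions whose diagnostic pattern is spatial rather than compositional
  (e.g. focal stiff rim) are outside the feature's discrimination.
* Short selections (<3 frames) propagate downstream: CV records require
  exactly 3 values and are skipped for short selections.
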