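# Methods

This note documents the models, the synthetic study design, and the
numerical and design choices behind `cineseg`.

## Problem setting

A thyroid ultrasound exam records a *cineclip*: a sweep of the transducer
across the neck in the transverse plane, yielding a T×H×W stack of B-mode
frames.  Clinically relevant structures are the thyroid gland, solid
nodules, and fluid-filled (anechoic) cysts.  Segmenting them per frame
enables automated volume estimation and TI-RADS-style feature reporting.
Two properties distinguish the task from ordinary video segmentation:
classes overlap (a nodule lies *within* the thyroid), and positives are
rare (nodules occupy roughly 2% of pixels and appear in roughly 35% of
frames), so both the output formulation and the loss must handle shared
classes and severe imbalance.

## Preprocessing

Frames are resized so the largest dimension equals a target (256 by
default), preserving aspect ratio; the unused canvas is filled with the
sentinel value −1, letting the models distinguish genuinely dark tissue
from filler.  Tissue intensities are scaled to [0, 1]; for clips the
scaling uses the global clip range so relative frame brightness is kept.
The tissue block is anchored top-left — a deterministic convention; nothing
downstream depends on the anchor.  Masks are resized with nearest-neighbour
interpolation and remain label-valued.

Dataset splits are patient-wise: no patient contributes clips to more than
one of train/validation/test.  Patients whose pathology cohort has fewer
than three members are routed to the training set (stratification is
meaningless for them and they must not contaminate evaluation); everyone
else is shuffled within their pathology stratum and apportioned by largest
remainder, so pathology proportions are approximately equal across splits.

## Models

**Static encoder.**  Input stem of three 3×3 convolutions (widths 32, 32,
64 at full width; first one stride 2) and a 3×3/stride-2 max-pool, then four
residual bottleneck stages with block widths [64 64 256], [128 128 512],
[256 256 1024], [512 512 2048] and repeats (1+2, 1+4, 1+23, 1+2).  The last
two stages replace striding with dilation rates 2 and 4, so the output
stride is 8.  All activations are LeakyReLU with slope 0.10; every
convolution is followed by batch normalization.  An ASPP module (1×1
branch, three dilated 3×3 branches, global-pooling branch; 256 filters)
aggregates context, and four fusion steps combine it with skip taps (after
the max-pool and after stages 1–3): each skip and the main path pass
through 1×1 convolutions of 128 filters, are concatenated, normalized and
activated.  Skips are bilinearly resized down to the stride-8 main-path
resolution before fusion; fusing at the larger skip resolution instead
would contradict the ×8 upsampling heads, so the smaller size is used.

**Heads.**  Each head restores full resolution from stride 8 and applies a
1×1 convolution and its activation (sigmoid for the thyroid head; softmax
over 3 channels — background, cyst, nodule — for the lesion head; softmax
needs an absence class).  The default upsampler is two transposed
convolutions, kernel 8/stride 4/pad 2 followed by kernel 4/stride 2/pad 1:
exact ×8 with every output pixel covered.  A single transposed convolution
with kernel 4 and stride 8 is also available (`upsample_head="prose"`) but
is not the default because stride > kernel provably leaves 3/4 of output
pixels unreachable by any input (dead stripes); a third variant
(`"table8"`) uses one kernel-8/stride-4 layer plus bilinear ×2.

**Recurrent model.**  The pretrained encoder is frozen (weights shared, not
copied, across the window's replicas; its batch-norm layers always run in
inference mode) and its heads are discarded.  A 6-frame window is split
into two groups of three; each group's per-frame fused features pass
through four bidirectional ConvLSTM blocks at dilations 1, 3, 5, 7.  A
block is a forward ConvLSTM and a backward ConvLSTM (the same cell run on
the time-reversed sequence, outputs re-reversed), concatenated, normalized
and activated.  The dilation applies to the convolutional kernels of all
gates.  The two groups' outputs are then merged in frame order into a
6-step sequence, over which one final forward and one final backward
ConvLSTM run; their concatenation feeds the dual heads, giving predictions
for all six frames with full cross-window information flow.  At the
default configuration the module contains 2 groups × 4 blocks × 2 + 2 = 18
ConvLSTM layers, each 3×3 with 32 filters.

Normalization inside the recurrent module uses the current batch's
statistics at every time step (no running averages): each step has its own
activation distribution, and a single running average fitted across steps
matches none of them.

**Initialisation.**  He-uniform for convolution kernels, orthogonal (per
gate) for ConvLSTM state kernels, forget-gate bias 1; all builders take an
explicit seed.

**Whole-clip inference.**  The static model runs frame-wise.  The recurrent
model slides its window over the clip (stride 3 by default); every window
contributes predictions for all its frames and overlapping contributions
are averaged.  The frame index sequence is reflect-padded so border frames
also occupy interior window positions, and each window is evaluated in both
temporal orientations (sequence reversal is a training augmentation, so
reversed windows are in-distribution); both choices symmetrize the
position-dependent prediction quality inherent to a windowed recurrent
model.  Because predictions depend on a frame's temporal context, exact
per-frame invariance under frame replication holds for the static path
only.

## Loss

For head h and class c with probability map p, binary target y and
per-pixel weight w (the weight of the pixel's *ground-truth* class), the
soft counts are TP = Σ w·p·y, FP = Σ w·p·(1−y), FN = Σ w·(1−p)·y,
TN = Σ w·(1−p)·(1−y).  A small ε (default 1e−6) is added to each count and
inside the square root of

MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and the loss is 1 − mean over heads of the per-head class-mean MCC
(thyroid head: one class; lesion head: cyst and nodule one-vs-rest;
background enters through its weight in the counts of the other classes).
Adding ε to the *counts* — not only under the root — is what keeps the
statistic informative when a class has no positives in the target: the
numerator becomes ε(TN+ε) − FP·ε, which strictly decreases in FP, so a
confident false positive costs more than a correct all-negative output and
receives a finite gradient.  With ε only under the root the numerator is
identically zero there and the gradient vanishes.

Default class weights down-weight the two majority classes (background
0.1, thyroid 0.1, cyst 1, nodule 1).  Inverse-pixel-frequency weighting is
available but not the default: combined with background down-weighting it
pushes the background weight to ~10⁻³ and produces unstable training and
severe over-segmentation of the minority classes.

Zero-denominator metric convention (reporting, not loss): any of the five
metrics with a vanishing denominator is 1 when the prediction is perfect
for that class (class absent in both prediction and truth) and 0 otherwise
(e.g. absent in truth but predicted).  The convention is applied uniformly.

## Training protocol

| stage | data | model | frozen | key settings |
|---|---|---|---|---|
| 1 | pre-training set (train + thyroid-only clips) | static, thyroid head only | — | frames, batch 6, Adam 1e−3, 12×20 steps |
| 2 | train | static, dual output (stage-1 weights) | — | 2/3 forced-nodule batches, Adam 1e−3, 10×20 |
| 3 | train | same model | through ASPP | full sequences, Adam 1e−4, 3×10 |
| 4 | train | recurrent (encoder frozen) | whole encoder | 6-frame windows, Adam 2e−3 ×0.94/epoch, 40×14 |

Augmentation per stage: stage 1 — horizontal flip 50%, rotation 25%/±15°,
translation 25%/±10%, intensity shift 10%/±5%, crop 100%/300 px; stage 2 —
flip, translation, intensity, crop 256 (plus the 2/3 forced-nodule
sampling); stage 3 — as stage 1 but rotation 50%/±5° and crop 256; stage
4 — flip 50% and sequence reversal 50%.  Geometric operations apply
identically to frames and masks; the intensity shift touches tissue pixels
only (the −1 sentinel is preserved); crops are taken after resizing and
clipped to the canvas, so a 300-px crop on a 256-px (or 64-px) canvas is a
no-op — the table is honoured at full scale and degrades gracefully at
desk scale.  "Intensity shift ±5%" is a single global additive offset of
the dynamic range (grayscale data; per-channel shifts are meaningless).

Stage 3 trains the static dual-output model frame-wise over whole clips
(the freezing boundary is: stem, stages and ASPP frozen; skip-fusion and
heads trainable).  Stage 4's learning rate (2e−3 decaying ×0.94 per epoch)
is deliberately higher than stage 3's: the recurrent module and its heads
train from scratch, and 1e−4 underfits badly within a desk-scale budget.
Sampler policies (forced-nodule batches, subsampling to a fixed nodule
rate, duplication oversampling) sit behind one interface; forced-nodule at
ratio 2/3 — two nodule batches for every three random batches — is the
default.

## Synthetic study design

The generator emulates the statistical structure of a clinical cineclip
dataset, not its acoustics.  A sweep is uniform-velocity planar slicing of
static 3-D ellipsoids, so structures grow/shrink and enter/leave the plane
across frames and every true volume is closed-form.  Reflectivity levels:
background 0.25, thyroid 0.55, nodules at thyroid ± 0.25 (hypo/hyper) or
equal (iso), cysts near 0 (anechoic).  Texture is fully developed speckle
approximated by unit-mean multiplicative Gamma noise with shape 4 (B-mode
magnitude after log-compression and scan conversion is smoother than raw
Rayleigh speckle; shape 4 gives a realistic ~50% pixel SD).  Margins:
*ill-defined* blurs the lesion's reflectivity edge (σ 1.5 px) in the image
only; *lobulated* modulates the boundary radius by 1 + a·sin(mθ), a ≤ 0.3,
m ∈ 3..6, in both image and mask.  Masks are always exact, noise-free
geometry.

A default single-nodule phantom solves its geometry from the prevalence
anchors (nodule frame span 35% of the sweep; in-plane radius from the 2%
pixel-count target).  Cohorts randomize geometry, echogenicity, margins and
malignancy labels, synthesize pathology strings (including one rare
pathology in cohorts of ≥ 5 patients) so stratified splitting is
exercised, render a fraction of patients on a wider canvas through the
resize-with-padding path so the −1 sentinel occurs naturally, and add a
couple of thyroid-only clips marked `pretrain`.

*Flicker* renders a lesion — and, with `thyroid_flicker_prob`, the whole
thyroid band — at 15% of its usual contrast in randomly chosen frames
while the ground truth persists.  It emulates transient obscuration
(shadowing, clutter, probe decoupling) and is the mechanism that makes the
temporal-benefit comparison meaningful: a frame-wise model cannot recover
an invisible structure, a windowed recurrent model can.  The protocol's
study condition trains on cohorts with lesion flicker 0.3 and thyroid
flicker 0.15 and evaluates temporal benefit on held-out cohorts with
flicker 0.45.

What the phantoms do **not** model: point-spread convolution, attenuation
and time-gain compensation, probe-geometry scan conversion, Hashimoto's/
Grave's texture, and real margin ambiguity.  Passing the phantom study
shows the pipeline is implemented correctly and that temporal context
helps under obscuration; it does not certify clinical performance.

## Desk-scale study sizes

The tested configuration uses width 1/8, 64×64 frames, block repeats
(1, 1, 2, 1), ASPP dilations (2, 4, 6) and 16 recurrent filters; cohorts
are 20 patients × 16 frames.  These sizes were chosen so a full protocol
run is minutes on one CPU while every architectural element (stem, four
stages, dilation, ASPP, fusion, dual heads, 18-layer recurrent module)
stays present.  Full-width 256×256 instantiation is configuration only.
At these sizes the protocol reaches held-out thyroid IoU ≈ 0.73–0.80
(3-seed range) and the recurrent model's nodule IoU on flickered phantoms
exceeds the static model's by ≈ +0.04–0.09 — both recomputed, never
stored, by the test suite and `scripts/acceptance.py`.

## Volume estimation

Integral volume is Σ_t area(mask_t)·dy·dx·dz (uniform-velocity assumption;
dz defaults to one frame-unit, physical spacing is accepted when known).
The ellipsoid approximation is (π/6)·L·W·H with L, W, H measured as
*caliper* extents: spans along the three axis lines through the region's
centroid, distances between outermost crossed voxel centers.  This mirrors
the clinical measurement and makes the approximation exact in the
digitized-ellipsoid limit; bounding-box extents would instead inflate
lobulated shapes (the box is set by lobe peaks).  Percent difference is
100·(ellipsoid − integral)/integral, so negative means the ellipsoid
underestimates — the expected direction for non-ellipsoidal shapes, and
the direction observed on lobulated phantom families.  Reports are
computed per class; plane projections are sums along each axis.

## Level-set baseline

DRLSE with the double-well distance regularizer, edge term and balloon
term; reference parameters Δt = 1.0, λ = 1, α = −0.9, ε = 2.75, 60 outer
iterations (10 evolution steps each, the inner-loop structure of the
original implementation) plus 10 refinement iterations with the balloon
off.  Seeds are ground-truth masks dilated by a 20-px disk; classes are
segmented independently per frame.  Conventions and deviations worth
noting:

- **Sign.**  Negative `alpha_area` *shrinks* the interior here (the seed is
  a dilation of the truth, so the front must contract onto the boundary);
  `flip_area_sign` restores the original formulation's convention.
- **Initialisation height.**  The binary-step height must exceed ε;
  otherwise δ_ε is nonzero over the entire plateau and the balloon erodes
  the interior globally instead of propagating a front.  Default ±3.0
  (> 2.75), mirroring the original pairing of step height 2 with ε = 1.5.
- **Edge indicator.**  g = 1/(1+|∇(G_σ∗I)|²) computed on the smoothed
  image range-normalised and scaled to 8-bit units (the formulation's
  implicit assumption); σ defaults to 1.5.  Range normalisation makes the
  result invariant to positive intensity scaling.
- μ defaults to the 0.2/Δt stability rule.

On a clean bright disk with the reference parameters the contour locks
onto the edge (IoU ≳ 0.9).  On speckle the edge indicator is small almost
everywhere, the front stalls near the dilated seed, and the baseline shows
the characteristic over-segmentation signature — recall near 1 with much
lower precision — degrading monotonically with speckle strength.

## Numerical core

`cineseg.nn` is a reverse-mode autodiff engine on numpy arrays:
convolutions and transposed convolutions via im2col/col2im with arbitrary
stride/dilation/padding, max-pooling with −∞ padding (inputs contain the
−1 sentinel), bilinear resize, batch normalization, ConvLSTM cells, and
Adam.  Gradients flow only through subgraphs containing trainable
parameters, so frozen encoders cost no backward work.  Every operation is
gradient-checked against central finite differences, and the convolution
forward is cross-checked against `scipy.signal.correlate`.  All training
is float32; determinism holds for fixed seeds and thread counts.

## Known limitations

- Phantom realism is structural, not acoustic (see above); absolute IoU
  values on phantoms do not transfer to clinical data.
- Cyst segmentation at desk scale is poor: cysts are small, present in
  fewer than half the clips, and desk-size validation splits may contain
  none (the zero-denominator convention then reports the sentinel).
- The recurrent model's per-frame predictions depend on window position;
  orientation-averaged inference mitigates but does not remove this.
- Whole-clip metrics aggregate per clip, then average over clips; per-frame
  aggregation is available via the underlying functions but is not the
  reporting default.
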