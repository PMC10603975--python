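# Methods

This note records how the package models the problem, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where the design was genuinely open.

## Data model and preprocessing

Images are single-channel intensity fields normalized to [0, 1] at load
time (integer data divided by the bit-depth maximum; RGB collapsed by
channel averaging). Acquisitions of arbitrary aspect (e.g. 1088×1388 px)
are mapped to the square network input by **center-cropping to the largest
inscribed square and resizing isotropically** (bilinear for images,
nearest-neighbor + re-threshold for masks). The crop anchor is a design
choice: a center square crop preserves proportions without anisotropic
distortion and is deterministic; cropping does discard the image margins,
which is acceptable because the organoid is centered in typical
acquisitions. Preprocessing is idempotent on already-square inputs and
never moves intensities outside the input range.

The classical fixed threshold (185) is stated on the 0–255 scale and
converted internally (185/255), so the package has a single intensity
scale throughout.

## Synthetic phantoms

The generator emulates the statistical structure of bright-field organoid
images, not their optics:

- **geometry** — an ellipse body (semi-axes drawn from
  `body_radius_range`, default 0.15–0.35 of the frame side, random
  orientation and a small center jitter) plus 0–4 bud disks centered on
  the body boundary (radius `bud_radius_fraction`·minor-axis, default
  0.3). The ground-truth mask is exactly this union; an empty union raises.
- **appearance** — dark body (default 0.30) on a bright field (0.80) with
  a slightly darker rim, a low-frequency background texture (amplitude
  0.03), and small Gaussian debris blobs placed strictly *outside* the
  mask (expected count `debris_density` = 30/frame) to reproduce the
  spreading cells that bait false positives. The contrast sign is
  configurable because real pixel values vary by microscope and medium.
- **noise** — per-pixel shot noise, `pixel ~ Poisson(λ·clean)/λ` with
  λ = 255 by default (an 8-bit photon-count scale); λ = None renders the
  noise-free scene. On flat patches the empirical variance equals
  mean/λ, which the tests verify.

Everything derives from `numpy.random.default_rng([seed, index])`, so a
dataset is bit-reproducible and each phantom depends only on its index.

What the phantoms do **not** model: 3-D structure, defocus and halo
artifacts of real bright-field optics, intensity distributions of any
particular microscope, or pathological-vs-physiological morphology
classes. Passing tests therefore demonstrate that the pipeline is
correct and that the methods behave sensibly on images with this
structure — not that any accuracy number transfers to real cultures.

## Augmentation strategies

Eleven named strategies form the experiment plan:

- `classic` — one transform per item drawn uniformly from horizontal/
  vertical flip, rotation by k·90°, and whitening. Rotations are
  restricted to multiples of 90° so masks need no interpolation.
  Whitening is per-image standardization rescaled into [0, 1] around 0.5
  (the rescale maps the extreme z-score to the interval edge, so the
  output mean is exactly 0.5); ZCA-style whitening was considered and
  left out as under-determined on single images.
- `gaussian`, `speckle`, `salt_pepper`, `shot` — direct noise injections
  (x+N(0,σ²); x·(1+N(0,σ²)); a fraction r of pixels forced to 0/1
  equiprobably; Poisson(λx)/λ), clipped to [0,1], masks untouched.
  Default magnitudes σ = 0.05, r = 0.05, λ = 255 — mild perturbations on
  the [0,1] scale chosen to degrade, not destroy, the image.
- `bce`, `bce_l1`, `ls`, `poisson`, `wass`, `pwass` — stand-ins for
  adversarial-autoencoder-generated groups. The generative models are
  prior work and are not re-implemented; each group is **emulated** as a
  classic transform plus a mild group-specific perturbation (e.g. `ls` →
  speckle σ = 0.04, `poisson` → shot λ = 500, `pwass` → Gaussian σ = 0.02
  + slight smoothing) and every output carries `emulated=True`. This
  preserves the 11-strategy topology of the experiment plan without
  claiming generative fidelity.

Group construction samples sources cyclically (every available original
contributes when the group is at least as large as the pool), records
`source_id` provenance on every item, and never draws from the excluded
(held-out) original. One transform is applied per item; stacking multiple
transforms is possible but not the default, since the single-transform
reading is the simpler interpretation of "randomly chosen" augmentation.

## Architectures as an ablation grid

Six boolean components span the grid; U-Net is all-off.

| flag | effect |
|---|---|
| `layer_reduction` | 5 resolution levels → 4 |
| `filter_reduction` | [64,128,256,512,1024] → [16,32,64,64] (padded with 64 when 5 levels are kept) |
| `kernel_reduction` | 2 feature convolutions per block → 1 |
| `ewise_skip` | skips join by element-wise addition (1×1 projections would be inserted on a channel mismatch; the named presets never need one; element-wise product is available behind `ewise_product`) |
| `stride_downsampling` | each block downsamples with a dedicated stride-2 convolution + batch-norm instead of max-pooling, and the bottleneck becomes dropout(0.5) + 2×2 max-pool |
| `softmax_activation` | 2-channel softmax head instead of 1-channel sigmoid |

Named presets: `munet` = layer+filter+kernel+stride (concatenation skips,
sigmoid head), `unet-mini` = all six. Three choices deserve comment:

1. **kernel vs stride interaction.** "Kernel reduction" is implemented as
   2→1 *feature* convolutions per block, and the stride flag *adds* the
   stride-2 downsampling convolution. Mu-Net (kernel+stride) therefore has
   exactly two convolutions per encoder block — one stride-1, one
   stride-2 — which is the published Mu-Net block layout; plain U-Net is
   unchanged. Decoder stages mirror the encoder's total convolution count,
   so Mu-Net's decoder has deconvolution pairs.
2. **Decoder bookkeeping.** The printed Mu-Net layer listing downsamples
   by 32 (four stride-2 convolutions plus the bottleneck pool) but its
   decoder as printed restores only ×16. The grid resolves this by making
   the decoder mirror the encoder exactly — one ×2 upsampling per ×2
   downsampling — and asserting output size == input size for every
   variant and side.
3. **Odd sizes.** With 'same' padding and ceil division, a 250 px input
   passes through sizes 125→63→32→16→8; at each skip junction the decoder
   tensor is center-cropped/zero-padded to the encoder tap's size (≤1 px
   at practical sides; more only for inputs near the 16 px minimum).
   Skip taps connect to the *pre-downsampling* (stride-1) output of each
   block, the resolution-matched choice.

Up-convolutions are ×2 nearest upsampling followed by a 2×2 convolution.
Parameter counts are closed-form per layer (k²·c_in·c_out + c_out for
convolutions, 2c for batch-norm scale/shift), and FLOPs count convolution
and batch-norm multiply-accumulates at 1 MAC = 2 FLOPs, pooling and
activations ignored — the convention is stated because published FLOP
figures for these networks are not mutually consistent, so the package
asserts only the *orderings* (params: UNet-Mini < Mu-Net < U-Net; FLOPs:
U-Net > Mu-Net ≥ UNet-Mini), which hold at every side. The numpy
backend's own parameter tally agrees with the closed forms for all 18
presets.

## Training

Adam (lr 1e-3) with binary cross-entropy on sigmoid-head logits (2-class
cross-entropy for softmax heads), batch size 4, at most 200 epochs.
Learning rate, batch size and epoch budget are exposed in
`TrainingConfig`; the published experiments state none of them, and these
defaults are the field's usual starting points. "Stop before the loss
plateaus" is operationalized as early stopping on the *training* loss
(patience 10 epochs, min-delta 1e-4) — with a single held-out test image
per fold there is no validation split to watch. The backend is plain
numpy, deterministic under the seed; GPU-style nondeterminism does not
arise.

The leave-one-out runner regenerates the augmentation group per fold
without the held-out image, records a per-fold manifest of
(item, source-original) pairs, asserts leakage-freedom from that manifest,
and can resume a run by skipping folds whose manifest hash already has a
result on disk.

Desk-scale defaults: tests and the acceptance script train at 32–64 px.
64 px preserves the full ÷32 downsampling path of the stride
architectures while keeping a 200-epoch single-image run under ten
seconds on one CPU; 250 px is the documented full-scale setting.

## Classical baselines

- **Threshold** — fixed 185/255 (dark foreground: strictly below) or
  Otsu; a constant image has no Otsu threshold and raises. Both modes
  exist because the fixed level is the documented default while Otsu is
  the named method; they coincide only on well-behaved histograms.
- **Region growing** — frontier pixels within 0.2 of the running region
  mean, frontier dilated by 1 px (8-connected) per iteration;
  deterministic. Default seeds: image center + the darkest pixel.
- **k-means + PSO** — global-best PSO (10 particles, 20 iterations,
  inertia 0.7, cognitive = social = 1.5) over intensity-space centroids
  minimizing within-cluster sum of squares, then Lloyd refinement from
  the swarm's best; with one particle and zero iterations this reduces
  exactly to k-means from that initialization. The PSO topology is a
  standard global-best swarm; the published variant's exact settings are
  not described. Foreground = the cluster whose mean matches the
  configured polarity.
- **Active contour** — morphological Chan–Vese from a centered circle,
  fixed iteration budget; the region-based energy makes the result
  invariant to positive intensity gain; zero iterations returns the
  initialization.
- **Watershed** — Sobel gradient after a σ=2 Gaussian presmooth
  (without it, shot noise fragments the markers); interior markers from
  the darkest 5% quantile (eroded), exterior markers on the border;
  foreground = interior basins.

On clean phantoms the five baselines all score well and k-means is among
the leaders but can be edged out by region growing (which is near-perfect
on noise-free two-level scenes); the test suite asserts k-means' strength
and *reports* the observed ranking rather than forcing the published
ordering, which was measured on real images that phantoms do not claim to
reproduce.

## Metrics and reports

All six scores derive from TP/FP/TN/FN pixel tallies. From one set of
counts F1 ≡ Dice algebraically, so any published table where they differ
must mix aggregations; the package therefore provides both routes —
per-image scores aggregated componentwise (median by default, mean
available) and pooled-count (micro-averaged) scores — and labels which is
which, without guessing which combination produced any particular printed
pair. Undefined ratios (empty ground truth or empty prediction) are NaN
with the metric named, and aggregation excludes them while reporting the
exclusion count; silent 0/1 conventions would corrupt medians on
40-image datasets. Overlays render TP white, TN black (or the dimmed
source image), FP/FN in configurable accent colors (pink/green default,
purple/cyan preset — both palettes appear in the literature's figures).

## Known limitations

- The numpy backend is single-threaded-ish and desk-scale; full-scale
  (250 px) leave-one-out runs are possible but slow, and the package makes
  no wall-clock or GPU-memory claims.
- Phantom realism is qualitative; no claim is made that Dice scores on
  phantoms predict scores on real bright-field cultures.
- Absolute parameter/FLOP figures depend on reconstruction choices the
  source material leaves open; only orderings are asserted.
- The emulated generative augmentation groups preserve experiment
  topology, not generative-model fidelity.
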