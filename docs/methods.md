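# Methods

This note documents the models and procedures implemented in `mapseg`,
the choices made where the design was genuinely open, and what the
bundled procedural fixtures can and cannot establish about real
endoscopy data.

## Problem setting

Supervised polyp segmentation needs pixel-wise annotations that are
expensive to obtain. `mapseg` instead trains a segmentation network
exclusively on polyp-free frames, under a one-class paradigm: lesions
are *simulated* on normal images, the network learns to segment the
simulated lesions, and at inference time real lesions are detected as
structured deviations from stored prototypes of healthy mucosa.

## Lesion simulation (SIMPO)

### Contour model

Lesion outlines are generated in polar coordinates as a perturbed unit
circle:

    r(theta) = 1 + sum_{i=1..n} xi_i * omega_i * sin(i*theta + phi_i)

with `n = 1000` harmonics, phases `phi_i ~ U(0, 2pi)`, amplitudes
`omega_i = 1/i^2` (a Brownian-noise spectrum that suppresses
high-frequency wiggles, giving smooth organic outlines) and deformation
scales `xi_i ~ U(0, 1)`. The deformation scale is ambiguous between a
per-harmonic draw (which the formula suggests) and a single shared
draw; both are implemented (`shared_scale=`) and the per-harmonic
reading is the default. Since `|r - 1| <= sum xi_i omega_i < pi^2/6`,
the radius can in principle reach zero; degenerate draws (min radius
<= 1e-3) are rejected and resampled.

Each contour is evaluated at 50 equally spaced angles, interpolated
with a *periodic* cubic spline (periodicity avoids a seam at theta=0)
to 500 boundary points, rescaled so the larger bounding-box side spans
90% of a 512x512 grid (the margin prevents clipping under later
transforms), centered, and polygon-filled. A template set of 1,000
such masks is pre-generated and persisted as 1-bit PNGs.

### Mask transformation and placement

A sampled template is downscaled to 60% of its extent, rotated
(uniform angle), elastically deformed (8x8 control grid of uniform
displacements, cubic-upsampled, max displacement 5% of the image side
— the deformation parameters are this package's choice), translated so
the lesion stays fully in frame, and globally scaled by
`s ~ U(0.2, 0.9)`. The anatomically valid region of the target frame
is computed by intensity thresholding: Otsu's threshold clamped into
[20, 50] gray levels (so uniformly bright frames remain fully valid
while near-black borders, overlays and corner thumbnails are always
excluded), followed by a 3x3 opening. The final mask is the
element-wise product of the valid region and the transformed template;
if the intersection is empty or keeps less than half the lesion area,
placement is re-drawn, up to 10 times, after which the frame is
reported unusable for that template.

### Content synthesis

Three strategies fill the mask, drawn with probabilities 0.4 / 0.4 /
0.2 (patch / texture / hybrid), mirroring NICE lesion types 1/3/2:

* **patch** — the frame itself, passed through the transform table
  below;
* **texture** — an external texture, recolored to the frame via
  iterative distribution transfer (below), then transformed;
* **hybrid** — `O = I (+) M . [(1-alpha) I' + alpha Tc']` with
  `alpha ~ U(0.3, 0.7)`.

Transform table (applied in order, each row independently with its
probability and a parameter uniform in its range): horizontal flip
p=0.5; vertical flip p=0.5; rotation [-90, +90] deg p=1.0; anisotropic
x-scaling [0.65, 1.0] p=0.5; intensity multiply (1.5, 2.0) p=1.0;
gamma (0.5, 1.5) p=1.0; Gaussian blur sigma=5 p=0.5; hue/saturation
shift [-10, +10] p=0.5. The same table feeds both the patch and the
texture branches. The intensity-multiply range only brightens; it is
kept as specified but is overridable in `SimpoConfig`.

Blending: the mask is Gaussian-blurred (sigma_s = 7 px, normalized to
peak 1), the base is darkened by `1 - 0.3 * B` (a soft shadow
concentrated along the contour), and the content is feathered in with
weight `mask * B`. Pixels where B is exactly zero (the blur kernel is
truncated at 3 sigma) are bit-identical to the source frame. The
shadow is applied once at compositing for every mode, including
hybrid. Shadow parameters are this package's defaults; none are
prescribed.

Reproducibility: every sampling stage consumes a dedicated child
stream spawned at a fixed slot index from the caller's generator, so
forcing alpha to 0 or 1 in the hybrid mode reproduces the pure patch
or texture output bit for bit under the same seed.

### Color transfer

Texture recoloring uses sliced (1D-projection) distribution transfer:
project both color clouds onto three orthonormal axes, match each 1D
marginal by quantile mapping (linear interpolation between order
statistics, stable-sorted ties), recombine the displacement in the
rotated frame, repeat. The first iteration uses the RGB axes, later
iterations seeded random rotations; 10 iterations by default, after
which the marginal mismatch plateaus on fixture images. A final
restoration step keeps the recolored low-pass (Gaussian, sigma = 2 px)
and adds back the original texture's high-pass, so structure comes
from the texture and color from the frame. The full variational
"regrain" of the original color-transfer literature is intentionally
not implemented; the Gaussian split satisfies the same contract at a
fraction of the complexity.

## Segmentation network

### Engine

The network is implemented on a small numpy engine written for this
package (`mapseg.nn`): reverse-mode autodiff over float32 arrays with
im2col convolution, batch normalization, bilinear up-sampling
(half-pixel-centres convention, realized as cached 1D interpolation
matrices), coordinate attention, and SGD with momentum. Gradients are
verified against float64 finite differences in the test suite. All
computation is CPU BLAS; a training step on an 8-image batch at
128 px takes a few seconds on one core.

### Architecture

A ResNet18 trunk (stem + stages 1-3) encodes a 256x256 input into
64/128/256-channel features at 64/32/16 px. The trunk is frozen and
always runs in eval mode. Pretrained weights are not bundled; the
encoder uses seeded He initialization, which suffices for every
property the package tests (discrepancy selection, attention locality,
learning on fixtures). Inputs are scaled to [0,1] and normalized with
the standard ImageNet channel statistics.

A memory bank stores the feature pyramids of N = 30 randomly selected
normal frames (without replacement, seeded); it is built once and
never updated. For an input pyramid `II`, each scale computes
channel-preserving squared-difference maps against every bank item and
keeps the one with the minimum total sum (`DI*`); the squared
(un-rooted) per-element form keeps the map smooth at zero, and the
channel structure is required because the attention maps average over
channels. Selection is per-scale independent. Spatial attention
cascades coarse to fine:

    M3 = mean_c DI3*,   M2 = mean_c DI2* . up(M3),   M1 = mean_c DI1* . up(M2).

`DI*` is concatenated with `II` per scale and fused by the multi-scale
feature-fusion module: 3x3 conv + BN + ReLU to widths 64/128/256,
coordinate attention (reduction 16, ReLU bottleneck), then coarse
scales are upsampled, 1x1-projected and added into finer scales. The
fused features are modulated by `Mn` and decoded with four x2
progressive-upsampling stages; the bottleneck (six 3x3 conv blocks of
width 480 at 1/16 resolution) concentrates capacity where compute per
parameter is lowest, and decoder widths are 144/48/32/16 with skip
connections from the two finer fused scales. A 1x1 conv + sigmoid
emits the probability map.

The reference widths were chosen so the instantiated network
reproduces the published model size: 19,049,905 parameters total,
16,267,121 trainable; the frozen encoder share is exactly 2,782,784
(= ResNet18 stem + stages 1-3 including batch-norm affine weights),
which pins down the frozen-encoder reading of the published
total-vs-trainable gap. The published architecture does not state its
internal widths; these are the package's reference configuration, not
a claim about the original implementation.

Because the encoder at random initialization has no calibrated
batch-norm statistics, its activations grow with depth; magnitudes
stay well inside float32 range and all downstream layers renormalize,
so this is benign.

## Training

Batches of 8 mix synthetic pairs and normal frames (all-zero masks)
50/50 — the ratio is unspecified upstream; a balanced split gives both
loss terms equal weight. The loss is pixel-mean focal loss with
alpha = 1, gamma = 4; the optimizer SGD (momentum 0.9, weight decay
3e-4), learning rate cosine-annealed from 0.01:
`lr(e) = lr0 (1 + cos(pi e / E)) / 2`. Default maximum 5,000 epochs.
Model selection keeps the checkpoint maximizing (IoU + Dice)/2 on a
held-out 20% split; validation ground truth is synthetic (pairs
generated from the held-out normals with their own fixed seed range),
since no real annotations exist in the one-class setting.

Since encoder and bank are frozen, the head's inputs for a fixed image
are constant; training therefore synthesizes a fixed pool of lesion
pairs up front and caches per-image head inputs, and each step only
runs the trainable head. Fresh streaming synthesis remains available
without the cache.

The learning check in the test suite uses a scaled-down configuration
chosen to fit a single CPU core: 200 procedural normal frames at
128 px, 8 memory samples, a pool of 48 synthetic training pairs and 12
validation pairs, 30 epochs of 3 steps. Under pinned seeds it reaches
a best validation Dice of ~0.56 (untrained baseline ~0.001), with the
best checkpoint typically early in the schedule — the selection
mechanism, not the final epoch, carries the result.

## Inference and post-processing

The probability map is computed at the model resolution and bilinearly
resized to the native frame size, thresholded at 0.5 (no threshold is
prescribed; it is exposed as an option), then refined: morphological
closing with a 5x5 square element, hole filling by border flood-fill
(identical to per-component filling for masks without border-touching
holes), and retention of the largest 8-connected component
(4-connected background for holes, the standard duality; ties keep the
first label in raster order). The refinement is idempotent and never
increases the component count.

## Evaluation

IoU and Dice from pixel confusion counts; two empty masks score 1.0 by
convention (the case never arises in lesion-only test sets). Dataset
aggregation reports mean and population-sd; the paired t-test uses the
sample sd (standard conventions). The group-sampling protocol draws,
per trial, five *disjoint* groups of 100 images without replacement
(disjointness is a choice; the protocol's source says only "randomly
sampled"), averages the metric per group and across groups, and
reports mean and sd over 50 trials. `add_bias_patch` paints a 64x64
black square over the lower-left corner — large enough to cover the
40x40 fixture thumbnail with margin; no size is prescribed upstream.

## Procedural fixtures

The fixture generator emulates two data sources so that the entire
pipeline builds and tests offline: reddish-pink multi-octave value
noise frames with vignette, specular highlights and an optional
green/black 40x40 corner thumbnail (emulating the acquisition bias of
public endoscopy corpora), and noise-based color textures. Palette
control is in HSV with wrap-around hue arithmetic.

What fixtures do not establish: real mucosal texture statistics,
camera optics, motion blur, real polyp morphology, or benchmark-level
segmentation scores. Passing tests demonstrate the pipeline's
contracts (determinism, compositing locality, discrepancy selection,
trainability), not clinical performance; reproducing published
benchmark numbers requires the real corpora and GPU-scale training and
is out of scope here.

## Numerical choices

* float32 throughout the network; float64 in the simulators and
  metrics where cost is negligible.
* Bilinear resampling uses the half-pixel-centres convention
  everywhere.
* Quantile matching interpolates linearly between order statistics.
* Focal-loss probabilities are clamped to [1e-7, 1 - 1e-7]; clamped
  pixels get zero gradient.
* Degenerate paired t-test variance raises instead of fabricating a
  p-value.
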