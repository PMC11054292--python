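# Methods

## The problem

A micron-scale bead imaged away from the focal plane of a wide-field
microscope produces a ringed defocus pattern whose structure encodes the
magnitude of the axial offset |z| and — because the illumination is
incoherent and broadband — also its sign: patterns above and below focus
differ visibly, which a single-wavelength laser system cannot provide.
This package implements an end-to-end system that exploits this:

1. a calibrated synthetic-scene generator that emulates the defocus
   library a microscopist would acquire with a piezo z-scan of
   immobilized beads;
2. a keypoint-detection network that maps a grayscale scene to per-class
   center heatmaps, sub-cell offset maps, and a normalized depth map;
3. sub-pixel decoding, size-class-resolved error evaluation, and
   frame-to-frame track linking with a stage-step z validation.

## The synthetic defocus model

A real calibration crops one feature image per (bead, z) stage position.
Here the single-bead pattern is parametric:

    I(r, z) = B + A · exp(−r² / 2w(|z|)²) · (1 + m(z) · cos(2π f(|z|) r))

with envelope width `w(|z|) = w0 + w1·|z|` (px), ring frequency
`f(|z|) = f0 + f1·|z|` (cycles/px), and modulation depth
`m(z) = m0·tanh(z/z_s)`, odd in z. The affine growth of `w` and `f`
makes the pattern's radial second moment strictly increase with |z| (the
ring system expands away from focus); the odd modulation term flips the
ring contrast across the focal plane, reproducing the above/below-focus
distinguishability of wide-field illumination. At z = 0 the pattern
reduces to a compact Gaussian spot.

Defaults (chosen once to look like 1-μm and 2-μm polystyrene beads at
23.3 nm/px and left alone): small bead — 64 px patch, w0 = 2.5 px,
w1 = 1.5 px/μm, f0 = 0.08, f1 = 0.012, m0 = 0.6, z_s = 2 μm; big bead —
96 px patch, w0 = 4.0 px, w1 = 2.2 px/μm, f0 = 0.06, f1 = 0.010, same
modulation. Patch sizes are set so the widest halo at |z| = 10 μm fits
inside the crop. Amplitude 0.5 and background 0.15 of the dynamic range;
additive Gaussian noise (default sd 0.02 of range) with clipping, applied
at scene level. Library patches themselves are noise-free, standing in
for the average of several exposures per stage position.

The z grid follows the segment-start convention: `[z_min, z_max)` in
steps of `z_step`, so the default −10…+10 μm scan at 50 nm yields exactly
400 positions per class and 800 library patches for two classes. An
inclusive grid would give 401 and contradict the printed counts.

What the generator does **not** emulate: Poisson shot noise and camera
gain structure, optical aberrations and field-dependent PSF variation,
refractive-index mismatch, bead polydispersity, and motion blur. Passing
tests therefore demonstrate that the pipeline recovers what this model
encodes, not that a network trained on these scenes transfers to a given
real microscope.

## Sub-pixel localization

Calibration centers come from the radial-symmetry method: every intensity
gradient of a radially symmetric spot points through its center, so the
center is the weighted least-squares intersection of the gradient lines
through inter-pixel midpoints (weights: squared gradient magnitude,
damped by distance to the magnitude centroid). The implementation uses
the normalized-direction line form rather than slope-intercept: the two
are algebraically equivalent, but slopes blow up for vertical gradient
lines and the finite-slope clamp measurably biases the result (~0.1 px on
an in-focus spot), while the direction form has no singularity. A
brute-force 0.01-px grid search over the same objective serves as the
oracle in the tests.

## Scene composition

Scenes start from a flat background; each particle is a library patch
chosen uniformly over (class, z-index), anchored at a uniform integer
position, given a uniform sub-pixel shift (cubic-spline interpolation),
and blended additively after subtracting the patch's own border-median
background — additive blending avoids paste seams. Placement is rejection
sampling under a pairwise separation of 0.6× the summed patch half-sizes
(configurable; 0 permits collisions). The annotation stores the shifted
calibrated center, so labels are exact by construction; a test
re-localizes isolated re-renders and requires agreement within 0.02 px.
Scene z values stay on the calibration grid, mirroring the library-based
construction. Dataset splits are floor-based with the remainder assigned
to train, so 12 000 images at 0.7/0.3 give the printed 8400/3600.

## Network

CenterXFNet: a ResNet-style backbone (grayscale stem) feeding a
feature-pyramid neck built from SPP+CSP and ELAN blocks, with three
heads on the final stride-4, 64-channel feature (full-scale model):

* SPP+CSP — cross-stage-partial split into two 1×1 branches; one passes
  parallel max-pools of window 5/9/13 (spatial size preserved) and a 3×3
  fuse; concat and 1×1 fuse to c2.
* ELAN — two 1×1 stems to c2/2; one stem feeds four 3×3 convolutions
  tapped after conv 2 and conv 4; the four tensors concatenate to 2·c2
  and fuse 1×1 to the stage output.
* Top-down path: deepest feature → SPP+CSP → nearest ×2 upsample → 1×1
  projection → concat with the lateral SPP+CSP output → 1×1 fuse → ELAN,
  repeated; the stride-4 lateral is a plain 1×1 projection.

With the ResNet50 backbone at 1024² input the stage geometry is, for
SPP+CSP 1–3, (c1, c2) = (2048, 256), (1024, 256), (512, 128) at
32²/64²/128², and for ELAN 1–3, (c1, c2, out) = (256, 512, 256),
(128, 256, 128), (64, 128, 64) at 64²/128²/256²; a shape audit derived
from the constructed layers (not a lookup table) is asserted in the
tests. The `tiny` backbone (widths 16/32/64/128) rescales the neck with a
floor so the final feature keeps 16 channels — a strict 1/16 scaling
would leave 4, too narrow to regress depth.

Heads are 3×3 conv → ReLU → 1×1 conv. The heatmap head ends in a sigmoid
with bias initialized to −2.19 (initial peak probability ≈ 0.1, the
standard focal-loss initialization); offset and depth heads are linear,
the depth bias starting at 0.5 (mid-range). An earlier sigmoid-bounded
depth head saturated at the ends of the z range and was replaced.

Input scenes are normalized by subtracting the per-image median and
dividing by a fixed constant (0.25 of the dynamic range). The median
tracks the background level whatever the particle count; the fixed scale
preserves pattern contrast across scenes. Per-image standardization by
the standard deviation was tried first and rejected: the sd grows with
the number of particles in view, so it rescales ring contrast — which is
exactly what encodes the sign and magnitude of z — and a model trained
on 4–5-particle scenes then misestimated depth by over a micron on
2-particle frames.

The whole network runs on a small reverse-mode autodiff engine over
numpy (`widefield_track3d.nn`): im2col convolution through one large
GEMM, separable max pooling, batch norm, nearest upsampling, concat, and
the two losses, each backward verified against central finite
differences. Training is Adam.

## Targets and losses

Encoding follows the keypoint-detection convention: each annotation's
center cell (floor(x/S), floor(y/S), S = 4) receives a unit peak; a
Gaussian splat with size-adaptive sigma (radius from the IoU-0.7 rule on
the pattern-footprint box, floor of one cell) fills the neighbourhood,
combined across objects by elementwise max. Offsets (x/S − cx, y/S − cy)
∈ [0, 1)² live at center cells. Depth is normalized affinely to [0, 1]
over the calibration range and — one deliberate departure from the
strict center-only convention — supervised over each object's splat
footprint (cells with splat > 0.3, at least the 3×3 block): depth is this
system's point, and center-only supervision starves the regression of
gradient signal at small batch counts. Decoding still reads depth at the
peak cell only. Out-of-range decoded depth is clamped to the calibration
range and flagged.

Losses: penalty-reduced pixelwise focal loss (α = 2, β = 4) on the
heatmap, L1 on masked cells for offset and depth, weighted 1 : 1 : 5 —
the depth term is emphasized for the same reason it gets the wider mask.
The loss is zero exactly at the ideal output (unit peaks, zero
elsewhere, exact offsets/depths at masked cells).

Decoding keeps 3×3 local maxima with ties retained (a two-cell plateau
yields two detections — covered by a test), takes top-k by score, then
applies the score threshold.

## Evaluation protocol

Detections are matched to ground truth one-to-one by Hungarian
assignment on xy distance with a gate (default 2 μm ÷ pixel scale);
class identity does not enter the distance but mismatches are recorded.
Horizontal error is the matched pair's xy distance × 23.3 nm/px;
vertical error is |Δz|; MAE is the plain mean, reported overall, per
bead class, and in 1-μm depth bins. Spurious and missed detections are
counted separately and never enter the MAE. With no matches the MAEs are
flagged undefined, never zero.

## Tracking

Greedy nearest-neighbour linking in xy (score order, same class
required, gate `max_disp`), with a globally optimal per-frame assignment
behind a flag; depth is deliberately excluded from the linking cost
because the z estimate is the quantity under validation. Tracks
unmatched for more than `max_misses` frames are lost. The z-trace
validator compares per-level median tracked z against commanded stage
offsets; MSD uses overlapping windows up to a quarter of the track
length (longer lags average too few pairs).

## Scaled-down study sizes

The full-scale configuration (ResNet50, 1024² inputs, 12 000 scenes,
hundreds of epochs) is what the architecture audit describes; the
*trained* experiments in the tests and the acceptance script run two
CPU-scale analogues chosen as the smallest studies that still exercise
the whole pipeline, both with the tiny backbone on 256² scenes with 4–5
particles, Adam at lr 2×10⁻³ (batch 2, ×0.1 decays at 70% and 90% of
epochs), flip augmentation, and 60 epochs:

* the localization study — z ∈ [−5, +5] μm at 0.25 μm (a 2-class,
  80-patch library), 36 scenes (27 train / 9 eval), three training seeds
  with the median-vertical-MAE seed reported;
* the stage-step study — the fixture scale, z ∈ [−2, +2) μm at 0.5 μm
  (16 patches), 40 scenes (30 train / 10 eval); its model tracks the
  fixture video, which steps one small and one big bead through offsets
  −2, −0.5, 0, +0.5, +1, +1.5 μm at five frames per level.

## Numerical choices and degenerate inputs

* Coordinates are 0-based with pixel centers at integers; x is the
  column, y the row; z is positive above the focal plane.
* All randomness flows from one root seed through named substreams
  (`util.substream`), so any single scene or frame is regenerable in
  isolation and identical seeds give bit-identical artifacts.
* The z-grid builder rejects ranges not divisible by the step, naming
  the remainder; uniform images raise a degenerate-input error in the
  localizer; over-crowded scenes raise an error carrying the count
  actually placed.
* Max-pool gradients route to the first argmax per window; 3×3
  suppression keeps ties.
* Matching uses a large-constant cost for gated-out pairs, then drops
  any assigned pair beyond the gate.
* Training aborts, keeping the last finite state, if the loss goes
  non-finite; the best-on-eval checkpoint (composite of both MAEs plus a
  miss/spurious penalty) is retained.

## Known limitations

* The parametric pattern model is not a diffraction computation (no Mie
  or angular-spectrum solution); it is a reproducible stand-in with the
  right monotonicity and symmetry structure.
* Real-data transfer is untested here by construction (no microscope
  data ships with the package); the published full-scale accuracies
  (horizontal ≈ 0.05 μm, vertical ≈ 0.2 μm) require real calibration
  crops and GPU-scale training and are out of scope for the CPU-scale
  study.
* The numpy engine is single-device and eager; it is sized for the tiny
  configuration. The full ResNet50 model constructs and audits, but
  training it at 1024² is impractical on one CPU.
* Collisions (overlapping patterns) degrade both detection and depth;
  the generator's separation default avoids them, and the linker has no
  mechanism to disambiguate identities through a collision.
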