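# Methods

This note documents the models implemented in `sbrnet`, the parameters
that matter, the numerical choices behind them, and what the synthetic
data generator does and does not emulate. It states no empirical number
that the test suite or `scripts/acceptance.py` does not itself compute.

## System geometry

The instrument being modelled is a miniature light-field fluorescence
mesoscope: a 3×3 microlens array (NA 0.05 per lenslet, magnification 0.52,
2.4 µm sensor pixels) forms 9 angular views of the sample in a single
frame. Object-space sampling is taken as the system's nominal 4.15 µm/px
throughout (the naive ratio 2.4/0.52 = 4.615 µm differs; the nominal value
is used consistently and the discrepancy noted here). The free-space
response is a z-indexed PSF stack from −225 to +375 µm in 25 µm steps
(25 planes); the reconstruction and ground-truth grid has 24 slices at
25 µm, so the synthetic default grid spans −225..+350 µm — the last
measured plane is dropped in favour of the network's 24 output channels.
Within the 2 mm field of view the response is treated as laterally
shift-invariant per slice, which is what makes the forward model a sum of
per-slice 2D convolutions.

### Synthetic PSF stand-in

When no measured stack is available, `synth_psf_stack` renders 9 isotropic
Gaussian spots per depth: spot *i* sits at its lenslet's baseline offset
plus a linear parallax `slope_i · z`, with standard deviation
`spot_sigma0 + defocus_slope · |z|`, and each plane is normalised to unit
sum. Defaults: baseline pitch 160 px on the 512-px working grid (72 px on
the 240-px desk grid), parallax slope magnitude 0.08 px/µm directed along
each lenslet's offset, `spot_sigma0 = 2 px`, `defocus_slope = 0.003 px/µm`.
The defocus slope is deliberately mild: the measured instrument's
free-space performance is roughly uniform across the axial range, so the
stand-in should not impose a strong focus gradient of its own — a steeper
slope (e.g. 0.01 px/µm) makes the shallowest slices optically worst and
confounds depth-performance analyses whose subject is attenuation, not
defocus. All of these are configuration values, not physical claims.

Coordinate conventions: pixel indices are 0-based, (u, v) = (row, col),
z increases away from the objective, the frame centre pixel is
`grid_px // 2`, and the convolution is cropped so that the PSF's centre
pixel lands on the source voxel (this matters on even-sized grids, where
`scipy`'s `mode="same"` is one pixel off that convention).

## Ground-truth volumes

Bead phantoms follow the training distributions: per volume one emitter
density is drawn from N(180, 118²) mm⁻³ and clipped at zero (a
non-positive draw gives an empty volume — clipping, rather than redrawing,
keeps zero attainable and biases the mean density by only ~+3 mm⁻³,
well inside sampling error); positions are uniform in the FOV cylinder;
diameters are N(15, 2²) µm truncated at 4 µm; brightnesses N(0.8, 0.1²)
clipped to (0, 1.2]. The truncation bounds are guards against nonphysical
draws and leave the means essentially unchanged.

Spheres are rasterised as brightness × indicator on a 5× finer grid
(0.83 × 0.83 × 5 µm voxels, centre-sampled) and 5×5×5 average-binned, so a
15 µm bead occupies a few binned voxels with partial-volume intensities.
Overlapping spheres combine by maximum, not sum, preserving the (0, 1.2]
brightness range the cross-entropy target assumes. Emitters extending
beyond the grid are clipped with a logged warning. Slice 0 is the sample
surface for attenuation purposes (z′ = 0).

## Background model

Scattering background is low-pass-filtered value noise: i.i.d. U(0, 1)
values on a coarse lattice (default spacing 25 px, a scale that gives
correlation lengths comparable to the blur range below), bilinearly
interpolated to a 600×600 canvas, Gaussian-blurred with a kernel size
drawn uniformly from [31.2, 48] µm, centre-cropped to the working grid,
multiplied by a circular Gaussian envelope, and max-normalised to [0, 1].
"Kernel size" is interpreted as the kernel's full width with σ = width/2,
converted to pixels at 4.15 µm/px; the envelope σ defaults to the FOV
radius (1000 µm) centred on the grid centre. The realised blur size and
seed are recorded on every generated background. The canvas-to-grid
mapping (blur first, then centre-crop) is a choice; the envelope is
applied on the cropped grid.

## Measurement composition and SBR control

The free-space term g₀ = Σ_z PSF(·;z) ⊛ V(·;z) and the background are
max-normalised independently. S̄ is the mean of the regional maxima of the
normalised free-space image (8-connected plateaus counted once,
border-touching plateaus excluded, maxima below 1% of the image max
discarded); B̄G is the mean of the normalised background over the circular
FOV support — post-envelope, so the SBR definition describes the
background actually added. Then

    α = (SBR − 1) · B̄G / S̄,    g = α·g₀ₙ + bgₙ,

which makes the recomputed SBR an algebraic identity of the stored
components. α is solved on noiseless terms; mixed Poisson–Gaussian noise
`f = g + sqrt(a·g + b)·ξ` is added after composition, with the background
counting as signal. The calibrated defaults a = 1.49e-4 ± 0.57e-4 and
b = 5.41e-6 ± 2.78e-6 live on the max-normalised intensity scale (their
magnitudes only make sense there). During online training augmentation a
and b are redrawn per batch from those normals, truncated below at 10% of
the mean. Beer–Lambert attenuation exp(−z′/ℓₛ) is applied to the *volume*
(emitter brightness decays with depth below the surface slice) before
convolution, for test data only — training data stays unattenuated so the
SBR of each training measurement remains exactly controlled.

## Views, refocusing, baseline background removal

The 9 views are fixed windows cut around each lenslet's baseline offset
(clipped windows are zero-padded and logged), which registers all views at
z = 0. Shift-and-add refocusing shifts view *i* by `−slope_i · z` (bilinear
subpixel interpolation, edge replication) and *averages* the 9 views, so
the refocused branch shares the views' intensity scale. The traditional
baseline preprocessing subtracts a morphological-opening background
estimate (disk radius 12 px ≈ twice the largest bead image radius) and
clips at zero; the operator is isolated behind one function so a Gaussian
high-pass or rolling ball can be swapped in.

## Network, loss, training

Dual-branch 2D ResNet with depth as channels. Each branch: one 3×3
expansion convolution (9→W or 24→W), N ResBlocks of [3×3 conv, BN, ReLU,
3×3 conv, BN] with identity skips, and a long skip from the first block's
input to the last block's output; branches fuse by elementwise summation
(the simplest symmetric choice); a final 3×3 convolution squeezes W→24 and
a sigmoid maps to [0, 1] (implied by cross-entropy on [0, 1] targets). All
convolutions are bias-free and He-initialised; the output layer's weights
are scaled by 0.1 at initialisation so the sigmoid starts unsaturated —
with sparse targets a saturated start wastes a long stretch of training
collapsing to the all-background solution. The forward path crosses
1 + 2N + 1 convolutions (42 at the full scale N = 20, width 48); the
stacked-conv receptive field is 2·(2N+2)+1 px. The loss is mean binary
cross-entropy with predictions clamped to [1e-7, 1−1e-7]; the ground-truth
target is either the continuous binned intensity clipped to [0, 1]
(default) or binarised occupancy — binarisation is the right choice when
detection at a fixed 0.5 threshold is the downstream metric, since
partial-volume bead voxels rarely exceed 0.5 on the continuous scale.

Training: Adam (lr 1e-3 default, cosine annealing with a 30-epoch
period), random patch positions per step, online randomised MPG noise on
the inputs (disabled for variants trained on preprocessed data), and
per-channel variance stabilisation — each of the 9 view channels and 24
refocused channels is standardised by its training-split mean/std (std
floored at 1e-6), with the statistics stored in the checkpoint and applied
identically at inference. The full-scale protocol (500 pairs, 80/20
split, 224-px patches, batch 12) ships as `TrainConfig.full()`; it is not
the default because it needs GPU-class compute. The entire network stack
is implemented in NumPy (im2col convolutions, hand-derived backward
passes, verified against finite differences in the test suite), which is
exactly deterministic for a given seed.

Inference is a full-frame forward pass; an overlap-tiled mode exists and
matches the full pass away from tile borders.

## Detection-based evaluation

Predicted volumes are thresholded at 0.5, 26-connected components smaller
than 2 voxels are dropped, and intensity-weighted centroids become
detections. Matching to ground-truth emitters is an optimal one-to-one
assignment (minimum total 3D distance) restricted to pairs within 2 px
laterally (~8.3 µm, half a 15 µm bead) and 1 slice (25 µm) axially;
unmatched detections are false positives binned by predicted slice (a
false positive has no true depth), unmatched emitters false negatives
binned by true slice. Per-depth precision/recall/F1 are averaged across
samples with standard errors, against both physical depth and normalized
depth z′/ℓₛ; slices with neither ground truth nor predictions are
undefined for that sample and excluded from averages (F1 is 0 when
only one side is empty). These tolerance choices are fixed defaults
exposed in the API.

The patch-PCA domain analysis pools 32×32 patches centred on emitters
from several measurement domains, fits one PCA, and compares per-domain
projections on the first two components.

## Desk-scale study design

All behavioural tests run a reduced configuration chosen once: a 240-px
working grid with 72-px lenslet pitch and 96-px view windows (the full
parallax range stays well inside the window, and the whole 200 µm FOV
disc is visible in every view), 12 training pairs, a 3-ResBlock /
width-16 network trained ~2100 Adam steps on 32-px patches (lr 3e-3,
binarised target), and evaluation phantoms at a fixed SBR of 2.0 with
8 samples per scattering length ℓₛ ∈ {80, 160, 320} µm. Two quantities
are rescaled along with the problem size. Test phantoms use a higher
emitter density (2000 mm⁻³) than the 180 mm⁻³ training default because
the desk FOV is ~100× smaller in volume than the instrument's — at the
nominal density a desk volume holds ~3 beads, too few for per-depth
statistics. And the desk parallax slope is 0.04 px/µm rather than the
0.08 px/µm working-grid default: at full scale the maximal parallax shift
is about two thirds of the 20-block network's receptive-field radius,
while the reduced network's receptive field is ~5× smaller, so an
unscaled slope would pose a relatively much harder geometric inference
problem than the instrument's. Evaluating at fixed SBR mirrors the
per-SBR structure of the full-scale analysis.

## What the generator emulates, and what it does not

It emulates: slice-wise shift-invariant light-field image formation,
heterogeneous low-frequency scattering background with controlled SBR,
signal-dependent sensor noise, ballistic-photon attenuation with depth,
and bead-like fluorescent targets. It does not emulate: scattering-induced
PSF broadening (negligible at NA 0.05 over the depths of interest),
optical aberrations, refraction at non-planar sample interfaces,
autofluorescence spectra, depth-dependent background statistics, or
non-spherical structures such as neurites. Consequently, passing tests
demonstrate the internal consistency of the simulator-training-evaluation
loop and the physics it encodes — not performance on real tissue, which
additionally stresses out-of-distribution robustness.

## Degenerate inputs and tie-breaks

A constant image has no regional maxima (border rule) and is rejected by
the mean-peak estimator; zero-max images cannot be composed; two
detections equidistant from one emitter resolve by the global minimum-cost
assignment (at most one matches); empty detection results are valid and
score zero recall; a zero-density draw produces an empty volume whose
free-space measurement is all zeros (and is redrawn where a nonzero
measurement is required). Subpixel view shifts use bilinear interpolation
with edge replication; binning uses exact reshape-mean; all stochastic
paths take an explicit `numpy.random.Generator`.

## Known limitations

The NumPy network is CPU-sized: the full 20-block/width-48 configuration
builds and runs forward passes (the architecture audits exercise it) but
training it at the full-scale protocol is out of reach here. Desk-scale
training yields detection F1 well below the full-scale regime, so
behavioural tests assert ordering properties (trained model beats the
background-removal baseline; F1 decays with normalized depth; curves for
different ℓₛ collapse within uncertainty) rather than absolute scores.
The collapse property is only partially attained by the desk model: full
collapse presupposes depth-uniform free-space skill, and the reduced
network's skill retains some dependence on absolute slice position, so
curves for different ℓₛ diverge at some normalized depths. The suite
asserts the property at full strength regardless, and reports the
measured agreement when it fails.
The refocusing and background-removal operators are deliberate,
documented choices among the several variants in common use (aperture
weighting, Fourier-slice refocusing, rolling-ball or high-pass background
estimation), and the synthetic PSF is a geometric stand-in for measured
system responses.
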