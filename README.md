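# sbrnet — simulator-trained descattering for light-field fluorescence

Tissue scattering is the depth limit of one-photon fluorescence imaging:
ballistic photons from an emitter at depth *z* below the surface attenuate
as exp(−*z*/ℓₛ) (ℓₛ the scattering length), while non-specific and scattered
fluorescence pile up into a strong heterogeneous background. The result is a
measurement with a signal-to-background ratio (SBR) barely above 1, in which
neither a human nor a classical background-removal pipeline can separate
deep emitters from the haze. Light-field microscopes make things both better
and worse: a single frame through a 3×3 microlens array carries 9 angular
views of the whole volume (so 3D comes from one shot), but the 2D→3D
inversion is ill-posed and scattering worsens its conditioning.

`sbrnet` is a complete, CPU-sized implementation of the simulator-trained
approach to this problem, aimed at researchers who want to study or extend
it without the instrument: every training pair is synthesized by a physics
forward model, a dual-branch residual network is trained purely on that
synthetic data, and performance is scored by 3D emitter detection versus
depth and scattering length.

## The model

A scattering light-field measurement is composed as

```
g(u,v) = α · Σ_z  PSF(u,v;z) ⊛ V(u,v;z)  +  BG(u,v)
```

where ⊛ is 2D convolution, `PSF(·;z)` the depth-indexed free-space system
response (measured stack, or a synthetic 3×3-parallax stand-in), `V` the
ground-truth bead volume (spheres ~N(15, 2²) µm diameter, brightness
~N(0.8, 0.1²), density ~N(180, 118²) mm⁻³, rasterized on a 5× fine grid and
5×5×5 average-binned), and `BG` low-pass-filtered value noise under a
circular Gaussian envelope — a cheap, generalizable model of scattering
background. With the free-space term and background each normalized to
[0, 1], the SBR is defined through the mean emitter peak S̄ and the mean
background B̄G:

```
SBR = (α·S̄ + B̄G) / B̄G        ⇒       α = (SBR − 1) · B̄G / S̄
```

so α is solved in closed form for any target SBR (training draws
SBR ~ U(1.1, 3.0)). Sensor noise is mixed Poisson–Gaussian,
`f = g + sqrt(a·g + b)·ξ` with calibrated a = 1.49e-4, b = 5.41e-6; test
phantoms additionally receive Beer–Lambert attenuation exp(−z′/ℓₛ).

The reconstruction network takes the two equivalent forms of one
measurement — the 9 registered lenslet views and the 24-slice shift-and-add
refocused volume — through two ResNet branches (3×3 convs, batch norm,
bias-free, He init), fuses them by summation, and squeezes to a 24-slice
volume in [0, 1] through a sigmoid. At full scale (20 ResBlocks
per branch, width 48) the forward path crosses 42 3×3 convolutions.
Training minimizes voxel-wise binary cross-entropy with Adam and cosine
annealing. The implementation is pure NumPy with hand-written
backpropagation, sized so the full loop runs on one CPU; see
`docs/methods.md` for every numerical choice.

## Worked example

`examples/` holds one short script per capability. For instance:

```
$ python examples/01_compose_measurement.py
emitters              : 38
mean peak signal S    : 0.4064
mean background BG    : 0.6636
alpha for SBR 1.5     : 0.8164
recomputed SBR        : 1.500000000
noisy frame range     : [0.1680, 1.5709]
```

38 beads were drawn for one volume; their mean free-space peak (S̄ = 0.41)
and the mean background (B̄G = 0.66) give α = 0.82 for a target SBR of 1.5,
and recomputing the SBR definition from the stored components returns the
target exactly.

```
$ python examples/02_refocus_and_localize.py
true source depth     : +125 um
sharpest slice        : z = +125 um
peak ratio best/worst : 7.62
```

Shift-and-add refocusing recovers a point source's depth to the exact
25 µm slice: only at the true depth do all 9 parallax-shifted views align.

`03_noise_calibration.py` recovers the noise parameters from corrupted
images (slope error < 0.1%); `04_train_and_evaluate.py` runs the full
train-and-score loop at toy scale.

A thin CLI wraps the same library calls for shell use:
`sbrnet simulate-psf | simulate-dataset | refocus | train | reconstruct |
evaluate | domain-pca` (see `sbrnet --help`).

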