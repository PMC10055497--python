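"""Scattering forward model: composition, SBR control, attenuation, noise.

A scattering light-field measurement is modelled as

    g(u, v) = alpha * sum_z PSF(u, v; z) (*) V(u, v; z) + BG ,

a laterally shift-invariant free-space term plus a synthetic scattering
background, where (*) is a 2D convolution, V the ground-truth volume, BG
the background and alpha a scalar controlling the signal-to-background
ratio.  With the free-space term and background each max-normalised to
[0, 1], the SBR of the composed measurement is defined as

    SBR = (alpha * S_bar + BG_bar) / BG_bar ,

where S_bar is the mean regional-maximum peak of the free-space term and
BG_bar the mean background over the FOV support, so alpha follows in closed
form from a target SBR.  Test (not training) volumes additionally receive
Beer-Lambert ballistic attenuation exp(-z'/l_s) with depth z' below the
sample surface and scattering length l_s.  Sensor noise is mixed
Poisson-Gaussian: f = g + sqrt(a*g + b) * xi with per-pixel standard-normal
xi and calibrated a, b (the background counts as signal for the noise).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.morphology import local_maxima

from .background import BGImage
from .optics import PSFStack
from .volume import GroundTruthVolume

__all__ = [
    "Measurement",
    "NoiseParams",
    "AttenuationParams",
    "free_space_measurement",
    "mean_signal",
    "solve_alpha",
    "compose_measurement",
    "apply_attenuation",
    "add_mpg_noise",
]

# Calibrated mixed Poisson-Gaussian noise parameters (max-normalised scale).
NOISE_A = 1.49e-4
NOISE_B = 5.41e-6
NOISE_A_STD = 0.57e-4
NOISE_B_STD = 2.78e-6

PEAK_FLOOR_FRACTION = 0.01  # regional maxima below 1% of image max are discarded


@dataclass(frozen=True)
class NoiseParams:
    """Poisson slope ``a`` and Gaussian floor ``b`` with calibration spreads."""

    a: float = NOISE_A
    b: float = NOISE_B
    a_std: float = NOISE_A_STD
    b_std: float = NOISE_B_STD

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("noise parameters must be nonnegative")

    def draw(self, rng: np.random.Generator) -> "NoiseParams":
        """Randomised parameters for online training augmentation.

        Draws a, b from normals at the calibrated means/stds, truncated below
        at 10% of the mean to stay physical.
        """
        a = max(rng.normal(self.a, self.a_std), 0.1 * self.a)
        b = max(rng.normal(self.b, self.b_std), 0.1 * self.b)
        return NoiseParams(a, b, self.a_std, self.b_std)


@dataclass(frozen=True)
class AttenuationParams:
    """Beer-Lambert ballistic attenuation: exp(-z'/scattering_length)."""

    scattering_length_um: float
    surface_slice: int = 0

    def __post_init__(self) -> None:
        if self.scattering_length_um <= 0:
            raise ValueError("scattering length must be positive")


@dataclass
class Measurement:
    """A composed measurement with full SBR/alpha/noise provenance.

    ``g`` is the noiseless composed image alpha*g0n + bgn (g0n, bgn the
    max-normalised free-space term and background), ``f`` the noisy image
    (equal to g until noise is applied), ``g0`` the un-normalised free-space
    term.
    """

    f: np.ndarray
    g: np.ndarray
    g0: np.ndarray
    bg: BGImage | None
    alpha: float
    sbr_target: float
    s_bar: float
    bg_bar: float
    kind: str = "scattering"  # {"free_space", "scattering", "background_removed"}
    noise: NoiseParams | None = None

    def __post_init__(self) -> None:
        if self.sbr_target < 1:
            raise ValueError("SBR must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if (self.alpha == 0) != (self.sbr_target == 1):
            raise ValueError("alpha = 0 iff SBR = 1")

    def recompute_sbr(self) -> float:
        """Re-evaluate the SBR definition from the stored components."""
        return (self.alpha * self.s_bar + self.bg_bar) / self.bg_bar


def free_space_measurement(volume: GroundTruthVolume, psf: PSFStack) -> np.ndarray:
    """Sum over depth of 2D convolutions of volume slices with PSF planes.

    Uses zero-padded same-size convolution; the slice count must equal the
    PSF plane count.
    """
    vox = volume.voxels
    if vox.shape[0] != psf.n_z:
        raise ValueError(
            f"volume has {vox.shape[0]} slices but PSF stack has {psf.n_z} planes"
        )
    out = np.zeros(vox.shape[1:], dtype=np.float64)
    h, w = vox.shape[1:]
    for k in range(psf.n_z):
        if not vox[k].any():
            continue
        full = signal.fftconvolve(vox[k], psf.planes[k], mode="full")
        # crop so the PSF's centre pixel (H//2, W//2) lands on the source
        # voxel (identical to mode="same" for odd sizes)
        pr, pc = psf.planes[k].shape[0] // 2, psf.planes[k].shape[1] // 2
        out += full[pr:pr + h, pc:pc + w]
    return np.clip(out, 0.0, None)


def mean_signal(g0: np.ndarray) -> float:
    """Mean regional-maximum peak intensity of a free-space measurement.

    Regional maxima are 8-connected plateaus strictly brighter than their
    surroundings (border-touching plateaus excluded, so a constant image has
    none); maxima below 1% of the image maximum are discarded and each
    plateau contributes its value once.  Returned on the input scale.
    """
    img = np.asarray(g0, float)
    peak = img.max()
    if peak <= 0:
        raise ValueError("image has no positive signal")
    mask = local_maxima(img, connectivity=2, allow_borders=False)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        raise ValueError("no regional maxima found (degenerate input)")
    values = np.array(ndimage.maximum(img, labels, index=np.arange(1, n + 1)),
                      ndmin=1)
    values = values[values >= PEAK_FLOOR_FRACTION * peak]
    if values.size == 0:
        raise ValueError("all regional maxima fall below the exclusion floor")
    return float(values.mean())


def solve_alpha(s_bar: float, bg_bar: float, sbr: float) -> float:
    """Scaling alpha achieving a target SBR: alpha = (SBR - 1) * BG_bar / S_bar."""
    if s_bar <= 0 or bg_bar <= 0:
        raise ValueError("S_bar and BG_bar must be positive")
    if sbr < 1:
        raise ValueError("SBR must be >= 1")
    return (sbr - 1.0) * bg_bar / s_bar


def compose_measurement(g0: np.ndarray, bg: BGImage, sbr: float) -> Measurement:
    """Compose a scattering measurement at a target SBR.

    g0 and the background are max-normalised independently; S_bar is the
    mean regional-maximum peak of normalised g0, BG_bar the mean normalised
    background over the FOV support; alpha is solved from the SBR definition
    and g = alpha * g0n + bgn.  No noise is applied here (f = g).
    """
    g0 = np.asarray(g0, float)
    g0_max = g0.max()
    bg_max = bg.pixels.max()
    if g0_max <= 0 or bg_max <= 0:
        raise ValueError("g0 and background must be nonzero")
    g0n = g0 / g0_max
    bgn = bg.pixels / bg_max
    s_bar = mean_signal(g0n)
    bg_bar = float(bgn[bg.support_mask()].mean())
    alpha = solve_alpha(s_bar, bg_bar, sbr)
    g = alpha * g0n + bgn
    return Measurement(f=g.copy(), g=g, g0=g0, bg=bg, alpha=alpha,
                       sbr_target=float(sbr), s_bar=s_bar, bg_bar=bg_bar,
                       kind="scattering")


def free_space_only(g0: np.ndarray) -> Measurement:
    """Wrap a free-space term as a Measurement (BG = 0, alpha = 1)."""
    g0 = np.asarray(g0, float)
    g0_max = g0.max()
    if g0_max <= 0:
        raise ValueError("g0 must be nonzero")
    g0n = g0 / g0_max
    s_bar = mean_signal(g0n)
    return Measurement(f=g0n.copy(), g=g0n, g0=g0, bg=None, alpha=1.0,
                       sbr_target=np.inf, s_bar=s_bar, bg_bar=0.0,
                       kind="free_space")


def apply_attenuation(volume: GroundTruthVolume,
                      att: AttenuationParams) -> GroundTruthVolume:
    """Attenuate slices by exp(-z'/l_s), z' the depth below the surface slice.

    Test-data only: training volumes are left unattenuated so the SBR of
    simulated measurements stays controlled.  Slices above the surface (if
    any) are unchanged.
    """
    nz = volume.voxels.shape[0]
    if not (0 <= att.surface_slice < nz):
        raise ValueError("surface_slice outside the volume")
    depths = (np.arange(nz) - att.surface_slice) * volume.config.z_step_um
    factors = np.exp(-np.clip(depths, 0.0, None) / att.scattering_length_um)
    return volume.with_voxels(volume.voxels * factors[:, None, None])


def add_mpg_noise(g: np.ndarray, params: NoiseParams, rng: np.random.Generator,
                  randomize: bool = False) -> np.ndarray:
    """Mixed Poisson-Gaussian noise: f = g + sqrt(a*g + b) * xi, clipped at 0.

    With ``randomize`` the calibrated uncertainties act as online training
    augmentation: a and b are redrawn per call.
    """
    g = np.asarray(g, float)
    if np.any(g < 0):
        raise ValueError("g must be nonnegative on the normalised scale")
    if randomize:
        params = params.draw(rng)
    sigma = np.sqrt(params.a * g + params.b)
    f = g + sigma * rng.standard_normal(g.shape)
    return np.clip(f, 0.0, None)
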