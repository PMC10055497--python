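"""Heterogeneous scattering-background synthesis.

Tissue scattering turns out-of-focus and non-specific fluorescence into a
strong, slowly varying background that buries low-contrast targets.  The
background model here is deliberately simple and generalises across
scattering conditions: value noise (uniform values on a coarse lattice,
interpolated to full resolution) is Gaussian low-pass filtered with a
kernel size drawn uniformly from 31.2-48 um, then multiplied by a circular
Gaussian envelope that accounts for the circular field of view and the
apodization of the optics, and finally max-normalised to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .optics import OpticsConfig

__all__ = [
    "BackgroundParams",
    "BGImage",
    "value_noise",
    "value_noise_from_lattice",
    "lowpass",
    "make_background",
]


@dataclass(frozen=True)
class BackgroundParams:
    """Knobs of the value-noise background generator.

    ``blur_kernel_*_um`` bound the uniformly drawn Gaussian kernel size,
    interpreted as the kernel's full width with sigma = width / 2 (converted
    to pixels at the object sampling).  ``envelope_sigma_um`` defaults to the
    FOV radius.  The raw noise canvas (600 x 600 px) is blurred first and then
    centre-cropped to the working grid.
    """

    lattice_spacing_px: int = 25
    blur_kernel_min_um: float = 31.2
    blur_kernel_max_um: float = 48.0
    envelope_sigma_um: float = 1000.0
    noise_size_px: tuple[int, int] = (600, 600)
    interp: str = "bilinear"  # {"bilinear", "cubic"}
    realized_blur_um: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.blur_kernel_min_um <= self.blur_kernel_max_um):
            raise ValueError("blur kernel bounds must satisfy 0 < min <= max")
        if self.lattice_spacing_px < 2:
            raise ValueError("lattice spacing must be >= 2 px")
        if self.interp not in ("bilinear", "cubic"):
            raise ValueError(f"unknown interpolation {self.interp!r}")


@dataclass
class BGImage:
    """One realised background on the working grid, max-normalised to [0,1]."""

    pixels: np.ndarray
    params_used: BackgroundParams
    seed: int | None = None
    fov_radius_px: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, float)
        if np.any(self.pixels < 0) or np.any(self.pixels > 1 + 1e-12):
            raise ValueError("background must lie in [0, 1]")

    def support_mask(self) -> np.ndarray:
        """Circular FOV support (full frame if no FOV radius recorded)."""
        h, w = self.pixels.shape
        if self.fov_radius_px is None:
            return np.ones((h, w), bool)
        rr = np.arange(h)[:, None] - h // 2
        cc = np.arange(w)[None, :] - w // 2
        return rr**2 + cc**2 <= self.fov_radius_px**2


def value_noise_from_lattice(lattice: np.ndarray, lattice_spacing_px: int,
                             shape: tuple[int, int], interp: str = "bilinear") -> np.ndarray:
    """Interpolate a given lattice to full resolution (test injection point)."""
    if lattice_spacing_px < 2:
        raise ValueError("lattice spacing must be >= 2 px")
    order = 1 if interp == "bilinear" else 3
    rows = np.arange(shape[0], dtype=float) / lattice_spacing_px
    cols = np.arange(shape[1], dtype=float) / lattice_spacing_px
    grid = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(np.asarray(lattice, float), grid,
                                  order=order, mode="nearest")
    return np.clip(out, 0.0, 1.0) if order == 3 else out


def value_noise(shape: tuple[int, int], lattice_spacing_px: int,
                rng: np.random.Generator, interp: str = "bilinear") -> np.ndarray:
    """Procedural value noise in [0, 1].

    Uniform[0,1] values are drawn on a lattice with ``lattice_spacing_px``
    pixel spacing and interpolated to ``shape``; with bilinear interpolation
    the output equals the lattice values exactly at lattice nodes.
    """
    if min(shape) < lattice_spacing_px:
        raise ValueError("image must be at least one lattice cell")
    n_r = shape[0] // lattice_spacing_px + 2
    n_c = shape[1] // lattice_spacing_px + 2
    lattice = rng.uniform(size=(n_r, n_c))
    return value_noise_from_lattice(lattice, lattice_spacing_px, shape, interp)


def lowpass(img: np.ndarray, kernel_size_um: float, sampling_um: float) -> np.ndarray:
    """Gaussian blur with sigma = kernel_size / sampling / 2 px, reflective edges."""
    if kernel_size_um <= 0:
        raise ValueError("kernel size must be positive")
    sigma_px = kernel_size_um / sampling_um / 2.0
    return ndimage.gaussian_filter(np.asarray(img, float), sigma_px, mode="reflect")


def _center_crop(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape
    if h < size or w < size:
        # small working canvases: tile reflectively to cover, then crop
        reps = (int(np.ceil(size / h)), int(np.ceil(size / w)))
        img = np.tile(img, reps)
        h, w = img.shape
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return img[r0:r0 + size, c0:c0 + size]


def make_background(params: BackgroundParams, config: OpticsConfig,
                    rng: np.random.Generator, seed: int | None = None) -> BGImage:
    """Draw one background: value noise -> blur -> crop -> envelope -> normalise.

    The realised blur size (uniform on [min, max] um) is recorded on the
    returned image's ``params_used``.
    """
    noise = value_noise(params.noise_size_px, params.lattice_spacing_px, rng,
                        params.interp)
    blur_um = rng.uniform(params.blur_kernel_min_um, params.blur_kernel_max_um)
    blurred = lowpass(noise, blur_um, config.object_sampling_um)
    img = _center_crop(blurred, config.grid_px)

    g = config.grid_px
    sigma_px = params.envelope_sigma_um / config.object_sampling_um
    rr = np.arange(g)[:, None] - g // 2
    cc = np.arange(g)[None, :] - g // 2
    envelope = np.exp(-(rr**2 + cc**2) / (2.0 * sigma_px**2))
    img = img * envelope

    peak = img.max()
    if peak > 0:
        img = img / peak
    return BGImage(img, replace(params, realized_blur_um=float(blur_um)),
                   seed=seed, fov_radius_px=config.fov_radius_px)
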