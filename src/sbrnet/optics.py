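"""System geometry and light-field PSF stacks.

The imaging system is a miniature light-field mesoscope whose sole imaging
element is a 3x3 microlens array (MLA): every sensor frame contains 9
angular views of the object volume.  Within the ~2 mm field of view the
response is slice-wise shift-invariant, so the system is fully characterised
by a z-indexed stack of on-axis point spread functions (PSFs), measured from
z = -225 um to z = +375 um in 25 um steps.

This module holds the geometry constants (:class:`OpticsConfig`), reads
measured PSF stacks from multi-page TIFFs, and provides a synthetic 3x3
parallax PSF model (9 Gaussian spots whose positions shift linearly with
depth) that stands in for measured free-space PSFs when no hardware data is
available.  At NA = 0.05 scattering-induced PSF broadening is negligible,
which is why a free-space PSF model suffices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "OpticsConfig",
    "PSFStack",
    "DisparityModel",
    "load_psf_stack",
    "save_psf_stack",
    "synth_psf_plane",
    "synth_psf_stack",
]


@dataclass(frozen=True)
class OpticsConfig:
    """Geometry of the light-field mesoscope and of the working grids.

    Lengths are in micrometres unless the name says pixels.  The object-space
    sampling is the system's nominal 4.15 um/px.  The reconstruction
    grid has ``n_slices`` axial slices at ``z_step_um`` spacing; the measured
    PSF range (-225..375, 25 um steps) has one plane more than the 24-slice
    reconstruction grid, so the synthetic default grid drops the last plane
    (z = -225..350) to match the network's 24 output channels.
    """

    sensor_pixel_um: float = 2.4
    magnification: float = 0.52
    object_sampling_um: float = 4.15
    lenslet_grid: tuple[int, int] = (3, 3)
    lenslet_pitch_px: float = 160.0
    na: float = 0.05
    z_min_um: float = -225.0
    z_max_um: float = 375.0
    z_step_um: float = 25.0
    n_slices: int = 24
    fov_diameter_um: float = 2000.0
    full_frame_px: tuple[int, int] = (2076, 3088)
    grid_px: int = 512
    view_px: int = 192

    def __post_init__(self) -> None:
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        n_steps = (self.z_max_um - self.z_min_um) / self.z_step_um
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("(z_max - z_min) must be an integer number of z steps")
        if self.n_slices * self.z_step_um > (self.z_max_um - self.z_min_um) + self.z_step_um:
            raise ValueError("n_slices exceeds the measured z range")
        if self.object_sampling_um <= 0:
            raise ValueError("object_sampling_um must be positive")
        if self.fov_diameter_um / self.object_sampling_um > max(
            self.grid_px, *self.full_frame_px
        ):
            raise ValueError("FOV does not fit on the working grid")

    # -- derived grids -------------------------------------------------
    @property
    def psf_z_um(self) -> np.ndarray:
        """Measured-PSF z grid (one plane more than the reconstruction grid)."""
        n = int(round((self.z_max_um - self.z_min_um) / self.z_step_um)) + 1
        return self.z_min_um + self.z_step_um * np.arange(n)

    @property
    def recon_z_um(self) -> np.ndarray:
        """Axial slice centres of the reconstruction / ground-truth grid."""
        return self.z_min_um + self.z_step_um * np.arange(self.n_slices)

    @property
    def depth_extent_um(self) -> float:
        return self.n_slices * self.z_step_um

    @property
    def fov_radius_px(self) -> float:
        return 0.5 * self.fov_diameter_um / self.object_sampling_um

    def fov_size_mm(self, shape_px: tuple[int, int] | None = None) -> tuple[float, float]:
        """Object-space extent (mm) of a pixel grid at the system sampling."""
        h, w = shape_px if shape_px is not None else self.full_frame_px
        s = self.object_sampling_um * 1e-3
        return (h * s, w * s)

    def desk(self, grid_px: int = 224, view_px: int = 64, lenslet_pitch_px: float = 72.0,
             fov_diameter_um: float = 200.0) -> "OpticsConfig":
        """A reduced working-grid configuration for CPU-scale experiments."""
        return dataclasses.replace(
            self, grid_px=grid_px, view_px=view_px,
            lenslet_pitch_px=lenslet_pitch_px, fov_diameter_um=fov_diameter_um,
        )


@dataclass
class PSFStack:
    """Depth-indexed stack of 2D system responses on the sensor grid."""

    planes: np.ndarray  # [n_z, H, W], nonnegative
    z_positions_um: np.ndarray
    provenance: str = "synthetic"  # {"measured", "synthetic"}
    normalization: str = "raw"  # {"per-plane-sum-1", "raw"}

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=np.float64)
        if self.planes.ndim != 3:
            raise ValueError("planes must be [n_z, H, W]")
        if len(self.z_positions_um) != self.planes.shape[0]:
            raise ValueError("z_positions length does not match plane count")
        if np.any(np.diff(self.z_positions_um) <= 0):
            raise ValueError("z positions must be strictly increasing")
        if np.any(self.planes < 0):
            raise ValueError("PSF intensities must be nonnegative")

    @property
    def n_z(self) -> int:
        return self.planes.shape[0]

    def normalized(self) -> "PSFStack":
        """Per-plane sum-1 normalised copy (zero planes left untouched)."""
        sums = self.planes.sum(axis=(1, 2), keepdims=True)
        sums = np.where(sums > 0, sums, 1.0)
        return PSFStack(self.planes / sums, self.z_positions_um,
                        self.provenance, "per-plane-sum-1")

    def subset(self, z_um: Sequence[float]) -> "PSFStack":
        """Restrict the stack to the given z planes (exact matches required)."""
        z_um = np.asarray(z_um, float)
        idx = []
        for z in z_um:
            hits = np.flatnonzero(np.isclose(self.z_positions_um, z))
            if hits.size == 0:
                raise KeyError(f"no PSF plane at z={z} um")
            idx.append(hits[0])
        return PSFStack(self.planes[idx], z_um, self.provenance, self.normalization)


@dataclass(frozen=True)
class DisparityModel:
    """Linear parallax model for the 9 lenslet views.

    ``lenslet_offsets_px[i]`` is view i's spot position (row, col) relative to
    the frame centre at z = 0; ``parallax_slope_px_per_um[i]`` its lateral
    drift per micrometre of depth.  Views are ordered row-major over the 3x3
    lenslet grid, so index 4 is the central lenslet with zero offset and zero
    slope, and offsets are antisymmetric under point reflection through it.
    """

    lenslet_offsets_px: np.ndarray  # [9, 2]
    parallax_slope_px_per_um: np.ndarray  # [9, 2]

    def __post_init__(self) -> None:
        off = np.asarray(self.lenslet_offsets_px, float).reshape(9, 2)
        slope = np.asarray(self.parallax_slope_px_per_um, float).reshape(9, 2)
        object.__setattr__(self, "lenslet_offsets_px", off)
        object.__setattr__(self, "parallax_slope_px_per_um", slope)
        if not (np.allclose(off[4], 0) and np.allclose(slope[4], 0)):
            raise ValueError("central lenslet must have zero offset and slope")
        if not np.allclose(off, -off[::-1]):
            raise ValueError("offsets must be antisymmetric through the centre")

    @classmethod
    def from_config(cls, config: OpticsConfig,
                    slope_magnitude_px_per_um: float = 0.08) -> "DisparityModel":
        """Regular 3x3 grid at the lenslet pitch; parallax along each offset."""
        ij = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)], float)
        offsets = ij * config.lenslet_pitch_px
        norms = np.linalg.norm(ij, axis=1, keepdims=True)
        directions = np.divide(ij, norms, out=np.zeros_like(ij), where=norms > 0)
        return cls(offsets, directions * slope_magnitude_px_per_um)


def load_psf_stack(path: str | Path, z_positions_um: Sequence[float],
                   normalize: bool = False) -> PSFStack:
    """Read a measured PSF stack from a multi-page TIFF (one page per plane).

    Raises ``ValueError`` if the page count does not match ``z_positions_um``
    or if the cast intensities contain negative values.
    """
    planes = np.asarray(tifffile.imread(str(path)))
    if planes.ndim == 2:
        planes = planes[None]
    z = np.asarray(z_positions_um, float)
    if planes.shape[0] != len(z):
        raise ValueError(
            f"TIFF has {planes.shape[0]} pages but {len(z)} z positions were given"
        )
    planes = planes.astype(np.float64)
    if np.any(planes < 0):
        raise ValueError("measured PSF contains negative intensities")
    stack = PSFStack(planes, z, provenance="measured")
    return stack.normalized() if normalize else stack


def save_psf_stack(stack: PSFStack, path: str | Path) -> None:
    """Write a PSF stack as a multi-page TIFF (dtype preserved)."""
    tifffile.imwrite(str(path), stack.planes, photometric="minisblack")


def _render_spots(shape: tuple[int, int], centers: np.ndarray,
                  sigma: float) -> np.ndarray:
    """Sum of unit-mass isotropic Gaussians rendered on a pixel grid."""
    h, w = shape
    img = np.zeros(shape, dtype=np.float64)
    half = int(np.ceil(6 * sigma)) + 1
    for r0, c0 in centers:
        rlo = max(int(np.floor(r0)) - half, 0)
        rhi = min(int(np.ceil(r0)) + half + 1, h)
        clo = max(int(np.floor(c0)) - half, 0)
        chi = min(int(np.ceil(c0)) + half + 1, w)
        if rlo >= rhi or clo >= chi:
            continue
        rr = np.arange(rlo, rhi, dtype=np.float64)[:, None]
        cc = np.arange(clo, chi, dtype=np.float64)[None, :]
        img[rlo:rhi, clo:chi] += np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)
        )
    return img


def synth_psf_plane(config: OpticsConfig, disparity: DisparityModel, z_um: float,
                    spot_sigma0_px: float = 2.0,
                    defocus_slope_px_per_um: float = 0.003) -> np.ndarray:
    """Synthetic PSF at depth z: 9 Gaussian spots with linear parallax.

    Spot i sits at ``centre + offset_i + slope_i * z`` with standard deviation
    ``spot_sigma0_px + defocus_slope * |z|`` (defocus widens spots away from
    focus).  The plane is normalised to unit sum.
    """
    if not (config.z_min_um - 1e-9 <= z_um <= config.z_max_um + 1e-9):
        raise ValueError(f"z={z_um} um outside [{config.z_min_um}, {config.z_max_um}]")
    g = config.grid_px
    center = np.array([g // 2, g // 2], float)
    centers = (center + disparity.lenslet_offsets_px
               + disparity.parallax_slope_px_per_um * z_um)
    sigma = spot_sigma0_px + defocus_slope_px_per_um * abs(z_um)
    img = _render_spots((g, g), centers, sigma)
    total = img.sum()
    if total <= 0:
        raise ValueError("all spots fell outside the grid")
    return img / total


def synth_psf_stack(config: OpticsConfig, disparity: DisparityModel | None = None,
                    spot_sigma0_px: float = 2.0,
                    defocus_slope_px_per_um: float = 0.003,
                    z_um: Sequence[float] | None = None) -> PSFStack:
    """Synthetic PSF stack on the reconstruction z grid (sum-1 planes)."""
    if disparity is None:
        disparity = DisparityModel.from_config(config)
    z = np.asarray(config.recon_z_um if z_um is None else z_um, float)
    planes = np.stack([
        synth_psf_plane(config, disparity, zi, spot_sigma0_px, defocus_slope_px_per_um)
        for zi in z
    ])
    return PSFStack(planes, z, provenance="synthetic", normalization="per-plane-sum-1")
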