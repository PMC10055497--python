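"""Ground-truth fluorescent bead volumes.

Volumes emulate sparse fluorescent beads suspended in a cylindrical sample:
emitter count follows a normal density (mean 180 beads/mm^3, std 118,
clipped at zero so a non-positive draw yields an empty volume), positions
are uniform in the field-of-view cylinder, diameters are normal around
15 um (std 2 um, truncated at 4 um) and brightnesses normal around 0.8
(std 0.1, clipped to (0, 1.2]).

Spheres are rasterised on a 5x finer grid (0.83 x 0.83 x 5 um voxels) and
5x5x5 average-binned to the working grid (4.15 x 4.15 x 25 um), so partial
voxels at sphere borders carry fractional intensity.  Overlapping spheres
combine by maximum, keeping voxel values within the (0, 1.2] brightness
range expected by the cross-entropy training target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .optics import OpticsConfig

__all__ = [
    "EmitterSet",
    "GroundTruthVolume",
    "sample_emitters",
    "rasterize_volume",
    "emitter_voxel_coords",
]

logger = logging.getLogger(__name__)

FINE_FACTOR = 5

# Training-distribution defaults
DENSITY_MEAN_PER_MM3 = 180.0
DENSITY_STD_PER_MM3 = 118.0
DIAMETER_MEAN_UM = 15.0
DIAMETER_STD_UM = 2.0
DIAMETER_MIN_UM = 4.0
BRIGHTNESS_MEAN = 0.8
BRIGHTNESS_STD = 0.1
BRIGHTNESS_MAX = 1.2


@dataclass
class EmitterSet:
    """Point-wise description of the beads in one volume.

    ``centers_um`` are (x, y, z) with x along image columns, y along rows,
    both measured from the optical axis; z on the reconstruction depth axis.
    """

    centers_um: np.ndarray  # [n, 3]
    diameters_um: np.ndarray  # [n]
    brightnesses: np.ndarray  # [n]
    fov_diameter_um: float
    depth_range_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.centers_um = np.asarray(self.centers_um, float).reshape(-1, 3)
        self.diameters_um = np.asarray(self.diameters_um, float).reshape(-1)
        self.brightnesses = np.asarray(self.brightnesses, float).reshape(-1)
        n = len(self.centers_um)
        if len(self.diameters_um) != n or len(self.brightnesses) != n:
            raise ValueError("emitter attribute lengths disagree")
        if n and (np.any(self.diameters_um <= 0) or np.any(self.brightnesses <= 0)
                  or np.any(self.brightnesses > BRIGHTNESS_MAX)):
            raise ValueError("diameters must be positive, brightness in (0, 1.2]")

    def __len__(self) -> int:
        return len(self.centers_um)

    @property
    def sample_volume_mm3(self) -> float:
        r_mm = 0.5 * self.fov_diameter_um * 1e-3
        depth_mm = (self.depth_range_um[1] - self.depth_range_um[0]) * 1e-3
        return np.pi * r_mm**2 * depth_mm

    @property
    def density_per_mm3(self) -> float:
        return len(self) / self.sample_volume_mm3


@dataclass
class GroundTruthVolume:
    """Binned emitter volume on the reconstruction grid [n_slices, H, W]."""

    voxels: np.ndarray
    emitters: EmitterSet
    config: OpticsConfig
    fine_voxel_um: tuple[float, float, float] = (0.83, 0.83, 5.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be [n_slices, H, W]")
        if np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be nonnegative")

    @property
    def z_positions_um(self) -> np.ndarray:
        return self.config.recon_z_um

    def with_voxels(self, voxels: np.ndarray) -> "GroundTruthVolume":
        return GroundTruthVolume(voxels, self.emitters, self.config, self.fine_voxel_um)


def _depth_bounds(config: OpticsConfig) -> tuple[float, float]:
    """Depth extent covered by the binned grid (half a slice beyond centres)."""
    lo = config.z_min_um - 0.5 * config.z_step_um
    return (lo, lo + config.depth_extent_um)


def sample_emitters(
    config: OpticsConfig,
    rng: np.random.Generator,
    density_mean: float = DENSITY_MEAN_PER_MM3,
    density_std: float = DENSITY_STD_PER_MM3,
    diameter_mean_um: float = DIAMETER_MEAN_UM,
    diameter_std_um: float = DIAMETER_STD_UM,
    brightness_mean: float = BRIGHTNESS_MEAN,
    brightness_std: float = BRIGHTNESS_STD,
) -> EmitterSet:
    """Draw one volume's worth of emitters.

    One density is drawn per volume from N(mean, std) clipped at zero and
    converted to a count through the FOV-cylinder volume; positions are
    uniform in the cylinder; diameters are truncated-normal (>= 4 um) and
    brightnesses normal clipped to (0, 1.2].
    """
    params = [density_mean, density_std, diameter_mean_um, diameter_std_um,
              brightness_mean, brightness_std]
    if not np.all(np.isfinite(params)) or density_mean <= 0:
        raise ValueError("generator parameters must be finite, density_mean > 0")

    zlo, zhi = _depth_bounds(config)
    radius_um = 0.5 * config.fov_diameter_um
    cyl_mm3 = np.pi * (radius_um * 1e-3) ** 2 * ((zhi - zlo) * 1e-3)

    density = max(rng.normal(density_mean, density_std), 0.0)
    n = int(round(density * cyl_mm3))

    # uniform in the cylinder: r = R*sqrt(u), theta uniform, z uniform
    u = rng.uniform(size=n)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    r = radius_um * np.sqrt(u)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    z = rng.uniform(zlo, zhi, size=n)

    diameters = rng.normal(diameter_mean_um, diameter_std_um, size=n)
    while np.any(diameters < DIAMETER_MIN_UM):  # truncate, do not clip: keeps shape
        bad = diameters < DIAMETER_MIN_UM
        diameters[bad] = rng.normal(diameter_mean_um, diameter_std_um, size=bad.sum())
    brightness = np.clip(rng.normal(brightness_mean, brightness_std, size=n),
                         1e-6, BRIGHTNESS_MAX)

    return EmitterSet(
        centers_um=np.column_stack([x, y, z]) if n else np.empty((0, 3)),
        diameters_um=diameters,
        brightnesses=brightness,
        fov_diameter_um=config.fov_diameter_um,
        depth_range_um=(zlo, zhi),
    )


def rasterize_volume(emitters: EmitterSet, config: OpticsConfig) -> GroundTruthVolume:
    """Render spheres on the 5x fine grid and 5x5x5 average-bin.

    Each sphere is brightness x indicator(|r - center| <= radius) sampled at
    fine-voxel centres; overlaps take the maximum.  Emitters outside the grid
    are clipped (logged), contributing only their in-grid part.
    """
    g = config.grid_px
    nz = config.n_slices
    fine_xy = config.object_sampling_um / FINE_FACTOR
    fine_z = config.z_step_um / FINE_FACTOR
    gf = g * FINE_FACTOR
    zlo, _ = _depth_bounds(config)
    half_um = 0.5 * g * config.object_sampling_um

    voxels = np.zeros((nz, g, g), dtype=np.float64)
    if len(emitters) == 0:
        return GroundTruthVolume(voxels, emitters, config,
                                 (fine_xy, fine_xy, fine_z))

    centers = emitters.centers_um
    radii = 0.5 * emitters.diameters_um
    # fine-grid coordinates of centres: x -> col, y -> row, z -> plane
    col_f = (centers[:, 0] + half_um) / fine_xy - 0.5
    row_f = (centers[:, 1] + half_um) / fine_xy - 0.5
    z_f = (centers[:, 2] - zlo) / fine_z - 0.5

    out = ((col_f - radii / fine_xy < -0.5) | (col_f + radii / fine_xy > gf - 0.5)
           | (row_f - radii / fine_xy < -0.5) | (row_f + radii / fine_xy > gf - 0.5)
           | (z_f - radii / fine_z < -0.5)
           | (z_f + radii / fine_z > nz * FINE_FACTOR - 0.5))
    if np.any(out):
        logger.warning("%d emitter(s) extend beyond the grid; clipped", int(out.sum()))

    zspan_planes = radii / fine_z
    for k in range(nz):
        plo, phi = k * FINE_FACTOR, (k + 1) * FINE_FACTOR
        hit = np.flatnonzero((z_f + zspan_planes >= plo - 0.5)
                             & (z_f - zspan_planes <= phi - 0.5))
        if hit.size == 0:
            continue
        slab = np.zeros((FINE_FACTOR, gf, gf), dtype=np.float64)
        for i in hit:
            rad = radii[i]
            rpx = rad / fine_xy
            rlo = max(int(np.ceil(row_f[i] - rpx)), 0)
            rhi = min(int(np.floor(row_f[i] + rpx)) + 1, gf)
            clo = max(int(np.ceil(col_f[i] - rpx)), 0)
            chi = min(int(np.floor(col_f[i] + rpx)) + 1, gf)
            if rlo >= rhi or clo >= chi:
                continue
            pz = np.arange(plo, phi, dtype=np.float64)[:, None, None]
            pr = np.arange(rlo, rhi, dtype=np.float64)[None, :, None]
            pc = np.arange(clo, chi, dtype=np.float64)[None, None, :]
            d2 = ((pz - z_f[i]) * fine_z) ** 2 + ((pr - row_f[i]) * fine_xy) ** 2 \
                + ((pc - col_f[i]) * fine_xy) ** 2
            ball = np.where(d2 <= rad**2, emitters.brightnesses[i], 0.0)
            np.maximum(slab[:, rlo:rhi, clo:chi], ball,
                       out=slab[:, rlo:rhi, clo:chi])
        voxels[k] = slab.reshape(FINE_FACTOR, g, FINE_FACTOR, g, FINE_FACTOR) \
                        .mean(axis=(0, 2, 4))

    return GroundTruthVolume(voxels, emitters, config, (fine_xy, fine_xy, fine_z))


def emitter_voxel_coords(emitters: EmitterSet, config: OpticsConfig) -> np.ndarray:
    """Emitter centres as fractional (slice, row, col) on the binned grid."""
    if len(emitters) == 0:
        return np.empty((0, 3))
    half_um = 0.5 * config.grid_px * config.object_sampling_um
    s = config.object_sampling_um
    zlo, _ = _depth_bounds(config)
    col = (emitters.centers_um[:, 0] + half_um) / s - 0.5
    row = (emitters.centers_um[:, 1] + half_um) / s - 0.5
    slc = (emitters.centers_um[:, 2] - zlo) / config.z_step_um - 0.5
    return np.column_stack([slc, row, col])
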