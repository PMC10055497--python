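"""View extraction, shift-and-add refocusing, and background removal.

A single sensor frame contains 9 sub-images, one per lenslet.  Cropping a
fixed window around each lenslet's baseline position registers the views to
a common object grid at z = 0; a point source at depth z then appears
displaced in view i by ``parallax_slope_i * z``.  Shift-and-add refocusing
undoes that parallax for a chosen depth and averages the 9 views, producing
a focal stack on the reconstruction z grid.

``remove_background`` is the traditional baseline preprocessing: a
morphological-opening estimate of the slowly varying background is
subtracted and the result clipped at zero.  The operator sits behind a
single interface so alternatives (Gaussian high-pass, rolling ball) can be
swapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening

from .forward import Measurement
from .optics import DisparityModel, OpticsConfig

__all__ = [
    "ViewStack",
    "RefocusedVolume",
    "extract_views",
    "refocus",
    "remove_background",
]

logger = logging.getLogger(__name__)


@dataclass
class ViewStack:
    """The 9 registered lenslet views, row-major over the 3x3 grid."""

    views: np.ndarray  # [9, h, w]

    def __post_init__(self) -> None:
        self.views = np.asarray(self.views, float)
        if self.views.ndim != 3 or self.views.shape[0] != 9:
            raise ValueError("views must be [9, h, w]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.views.shape[1:]


@dataclass
class RefocusedVolume:
    """Shift-and-add focal stack on the reconstruction z grid."""

    slices: np.ndarray  # [n_z, h, w]
    z_positions_um: np.ndarray

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, float)
        self.z_positions_um = np.asarray(self.z_positions_um, float)
        if self.slices.shape[0] != len(self.z_positions_um):
            raise ValueError("slice count does not match z grid")


def extract_views(measurement: Measurement | np.ndarray, config: OpticsConfig,
                  disparity: DisparityModel) -> ViewStack:
    """Crop the 9 lenslet sub-images into a registered view stack.

    A ``view_px`` window is cut around frame-centre + baseline offset for
    each lenslet; windows clipped by the frame border are zero-padded (and
    logged).  Raises if a window lies entirely outside the frame.
    """
    img = measurement.f if isinstance(measurement, Measurement) else np.asarray(
        measurement, float)
    h, w = img.shape
    vp = config.view_px
    half = vp // 2
    views = np.zeros((9, vp, vp), dtype=np.float64)
    for i, (dr, dc) in enumerate(disparity.lenslet_offsets_px):
        r0 = int(round(h // 2 + dr)) - half
        c0 = int(round(w // 2 + dc)) - half
        rlo, rhi = max(r0, 0), min(r0 + vp, h)
        clo, chi = max(c0, 0), min(c0 + vp, w)
        if rlo >= rhi or clo >= chi:
            raise ValueError(f"view window {i} lies outside the measurement")
        if (rlo, rhi, clo, chi) != (r0, r0 + vp, c0, c0 + vp):
            logger.warning("view %d clipped at the frame border; zero-padded", i)
        views[i, rlo - r0:rhi - r0, clo - c0:chi - c0] = img[rlo:rhi, clo:chi]
    return ViewStack(views)


def refocus(views: ViewStack, disparity: DisparityModel,
            z_um: Sequence[float]) -> RefocusedVolume:
    """Shift-and-add refocusing: align the parallax at each depth and average.

    View i is shifted by ``-parallax_slope_i * z`` with bilinear subpixel
    interpolation and edge replication, then the 9 shifted views are
    averaged (averaging keeps the refocused branch on the same intensity
    scale as the view branch).
    """
    z_um = np.asarray(z_um, float)
    nz = len(z_um)
    h, w = views.shape
    out = np.zeros((nz, h, w), dtype=np.float64)
    for k, z in enumerate(z_um):
        acc = np.zeros((h, w), dtype=np.float64)
        for i in range(9):
            shift_rc = -disparity.parallax_slope_px_per_um[i] * z
            if np.all(shift_rc == 0):
                acc += views.views[i]
            else:
                acc += ndimage.shift(views.views[i], shift_rc, order=1,
                                     mode="nearest")
        out[k] = acc / 9.0
    return RefocusedVolume(out, z_um)


def remove_background(image: np.ndarray, radius_px: int = 12) -> np.ndarray:
    """Subtract a morphological-opening background estimate, clipped at zero.

    The structuring element is a disk whose radius (default 12 px) is about
    twice the largest expected bead image radius, so beads are too small to
    survive the opening and are preserved in the difference.
    """
    img = np.asarray(image, float)
    if np.any(img < 0):
        raise ValueError("image must be nonnegative")
    estimate = opening(img, disk(radius_px))
    return np.clip(img - estimate, 0.0, None)
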