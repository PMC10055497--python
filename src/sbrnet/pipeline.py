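"""End-to-end dataset synthesis, bundling, and reproducibility manifest.

One training pair = (9 registered views, 24-slice refocused volume,
24-slice ground-truth volume) plus metadata.  The pipeline per pair:
sample emitters -> rasterise volume -> free-space measurement (PSF
convolution) -> background -> compose at a drawn SBR -> extract views ->
refocus -> crop the ground truth to the view window.  Variants:

* ``scattering`` (default): composed low-SBR measurement; noiseless
  views/refocused are stored, online noise is applied during training.
* ``free_space``: background off, alpha = 1.
* ``background_removed``: noise is applied offline to the scattering
  measurement, the background-removal baseline is run, then views/refocus
  are derived; no online noise should be used on this variant.

Seeds are hierarchical (master seed -> per-pair child streams) so any
single pair can be regenerated in isolation, and re-running with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import background as bg_mod
from . import forward as fwd
from . import lightfield as lf
from . import volume as vol_mod
from .background import BackgroundParams
from .optics import DisparityModel, OpticsConfig, PSFStack, synth_psf_stack

__all__ = ["SimulationConfig", "RunManifest", "generate_pair",
           "generate_pairs", "simulate_dataset", "load_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Resolved parameter tree for dataset synthesis."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    n_pairs: int = 500
    sbr_range: tuple[float, float] = (1.1, 3.0)
    variant: str = "scattering"  # {"scattering", "free_space", "background_removed"}
    density_mean: float = vol_mod.DENSITY_MEAN_PER_MM3
    density_std: float = vol_mod.DENSITY_STD_PER_MM3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("scattering", "free_space", "background_removed"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (1.0 <= self.sbr_range[0] <= self.sbr_range[1]):
            raise ValueError("SBR range must satisfy 1 <= low <= high")

    @classmethod
    def desk(cls, n_pairs: int = 20, seed: int = 0, **kwargs) -> "SimulationConfig":
        return cls(optics=OpticsConfig().desk(), n_pairs=n_pairs, seed=seed,
                   **kwargs)


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, file checksums."""

    config: dict
    seeds: dict
    version: str
    inventory: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_file(self, path: str | Path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.inventory[p.name] = digest

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))


def _crop_center(arr: np.ndarray, size: int) -> np.ndarray:
    h, w = arr.shape[-2:]
    r0, c0 = h // 2 - size // 2, w // 2 - size // 2
    return arr[..., r0:r0 + size, c0:c0 + size]


def generate_pair(config: SimulationConfig, psf: PSFStack,
                  disparity: DisparityModel,
                  rng: np.random.Generator,
                  density_mean: float | None = None,
                  attenuation: fwd.AttenuationParams | None = None,
                  add_noise: bool = False,
                  sbr: float | None = None) -> dict:
    """Synthesise one (views, refocused, gt, meta) pair.

    ``attenuation`` (test data only) applies Beer-Lambert decay to the
    volume before the measurement; ``add_noise`` corrupts the measurement
    with mixed Poisson-Gaussian noise before view extraction (used for test
    phantoms and the background-removed variant; the scattering training
    variant stores noiseless inputs and adds noise online instead).  ``sbr``
    pins the target SBR (test phantoms are scored per SBR); by default it is
    drawn uniformly from the configured range.
    """
    oc = config.optics
    emitters = vol_mod.sample_emitters(
        oc, rng, density_mean=density_mean or config.density_mean,
        density_std=config.density_std)
    volume = vol_mod.rasterize_volume(emitters, oc)
    meas_volume = (fwd.apply_attenuation(volume, attenuation)
                   if attenuation is not None else volume)
    g0 = fwd.free_space_measurement(meas_volume, psf)

    meta: dict = {"n_emitters": len(emitters), "variant": config.variant}
    if config.variant == "free_space":
        meas = fwd.free_space_only(g0)
        meta.update(alpha=1.0, sbr=None, bg_mean=0.0)
    else:
        bg = bg_mod.make_background(config.background, oc, rng)
        if sbr is None:
            sbr = float(rng.uniform(*config.sbr_range))
        meas = fwd.compose_measurement(g0, bg, sbr)
        meta.update(alpha=meas.alpha, sbr=meas.sbr_target, s_bar=meas.s_bar,
                    bg_bar=meas.bg_bar,
                    blur_um=bg.params_used.realized_blur_um)

    frame = meas.g
    if add_noise or config.variant == "background_removed":
        frame = fwd.add_mpg_noise(frame, fwd.NoiseParams(), rng)
        meta["noise"] = {"a": fwd.NOISE_A, "b": fwd.NOISE_B}
    if config.variant == "background_removed":
        frame = lf.remove_background(frame)

    views = lf.extract_views(frame, oc, disparity)
    refocused = lf.refocus(views, disparity, oc.recon_z_um)
    gt = _crop_center(volume.voxels, oc.view_px)
    if attenuation is not None:
        meta["scattering_length_um"] = attenuation.scattering_length_um
    return {
        "views": views.views,
        "refocused": refocused.slices,
        "gt": gt,
        "meta": meta,
        "emitters": emitters,
        "measurement": meas,
        "frame": frame,
    }


def generate_pairs(config: SimulationConfig, psf: PSFStack | None = None,
                   disparity: DisparityModel | None = None,
                   **pair_kwargs) -> list[dict]:
    """Generate ``config.n_pairs`` pairs with hierarchical per-pair seeds."""
    oc = config.optics
    disparity = disparity or DisparityModel.from_config(oc)
    psf = psf or synth_psf_stack(oc, disparity)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_pairs)
    return [generate_pair(config, psf, disparity,
                          np.random.default_rng(s), **pair_kwargs)
            for s in streams]


def simulate_dataset(config: SimulationConfig, out_path: str | Path,
                     psf: PSFStack | None = None) -> RunManifest:
    """Generate a dataset bundle and write it to HDF5 with a manifest.

    Layout: /views [N,9,h,w], /refocused [N,24,h,w], /gt [N,24,h,w],
    /meta [N] JSON strings.  The manifest records the resolved config, the
    master seed and a sha256 of the written file.
    """
    out_path = Path(out_path)
    pairs = generate_pairs(config, psf=psf)
    try:
        with h5py.File(out_path, "w") as f:
            f.create_dataset("views", data=np.stack(
                [p["views"] for p in pairs]).astype(np.float32))
            f.create_dataset("refocused", data=np.stack(
                [p["refocused"] for p in pairs]).astype(np.float32))
            f.create_dataset("gt", data=np.stack(
                [p["gt"] for p in pairs]).astype(np.float32))
            meta = [json.dumps(p["meta"]) for p in pairs]
            f.create_dataset("meta", data=meta,
                             dtype=h5py.string_dtype("utf-8"))
    except Exception:
        out_path.unlink(missing_ok=True)  # no partial bundles
        raise
    manifest = RunManifest(
        config=_config_dict(config),
        seeds={"master": config.seed},
        version="sbrnet 0.1.0",
    )
    manifest.add_file(out_path)
    manifest.write(out_path.with_suffix(".manifest.yaml"))
    return manifest


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=lambda o: list(o)
                                 if isinstance(o, tuple) else str(o)))


def load_dataset(path: str | Path) -> list[dict]:
    """Read an HDF5 bundle back into the in-memory pair-list form."""
    out = []
    with h5py.File(path, "r") as f:
        views = f["views"][...].astype(np.float64)
        refocused = f["refocused"][...].astype(np.float64)
        gt = f["gt"][...].astype(np.float64)
        meta = [json.loads(m) for m in f["meta"].asstr()[...]]
    for i in range(views.shape[0]):
        out.append({"views": views[i], "refocused": refocused[i],
                    "gt": gt[i], "meta": meta[i]})
    return out
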