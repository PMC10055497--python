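"""Dual-branch residual reconstruction network and its training loop.

The network maps a single light-field measurement to a 24-slice volume in
[0, 1].  It is a 2D ResNet in which depth lives on the channel axis, with
two branches taking equivalent forms of the measurement: the stack of 9
registered views (parallax information) and the 24-slice shift-and-add
refocused volume (focal-stack information).  Each branch expands its input
to ``width`` channels with a 3x3 convolution and runs ``n_resblocks``
residual blocks of [3x3 conv, batch norm, ReLU, 3x3 conv, batch norm] with
an identity skip, plus a long skip from the first block's input to the last
block's output.  The branches are fused by elementwise summation and a
final 3x3 convolution squeezes ``width`` channels to the 24 output slices,
followed by a sigmoid.  All convolutions are bias-free; weights use He
initialisation.  At the full-size specification (20 blocks, width 48) one
forward path crosses 42 3x3 convolutions.

Training minimises voxel-wise binary cross-entropy (promoting sparse
reconstructions), with Adam, a cosine-annealed learning rate, random patch
sampling, online mixed Poisson-Gaussian noise on the inputs, and a
variance-stabilising per-channel standardisation whose statistics are
computed once on the training split and reused verbatim at inference.

Variants trained elsewhere in the pipeline: the scattering-trained network
(raw low-SBR inputs, online noise), a free-space network and a
background-removed network, which train on preprocessed inputs with no
online noise.  The implementation is pure NumPy with hand-written
backpropagation, sized for CPU-scale experiments; the full-size
specification ships as a preset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forward import NoiseParams, add_mpg_noise
from .nn import Adam, BatchNorm2d, Conv3x3, Parameter, cosine_annealing_lr, sigmoid

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "NormStats",
    "SBRNet",
    "build_network",
    "bce_loss",
    "compute_normalization_stats",
    "variance_stabilize",
    "train",
    "reconstruct",
    "save_checkpoint",
    "load_checkpoint",
]

EPS_CLAMP = 1e-7


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters.

    ``full()`` is the full-scale configuration (20 ResBlocks per
    branch, width 48); ``desk()`` a CPU-scale one.  Convolution bias is
    always off.
    """

    n_resblocks_per_branch: int = 20
    width_channels: int = 48
    in_channels_views: int = 9
    in_channels_refocus: int = 24
    out_channels: int = 24
    use_batchnorm: bool = True

    def __post_init__(self) -> None:
        if min(self.n_resblocks_per_branch, self.width_channels,
               self.out_channels) < 1:
            raise ValueError("network dimensions must be positive")

    @classmethod
    def full(cls) -> "NetworkSpec":
        return cls()

    @classmethod
    def desk(cls, n_resblocks: int = 4, width: int = 16) -> "NetworkSpec":
        return cls(n_resblocks_per_branch=n_resblocks, width_channels=width)

    @property
    def forward_conv_count(self) -> int:
        """3x3 convolutions along one branch's forward path.

        One expansion layer, two per ResBlock, one final fusion layer:
        1 + 2*N + 1 (= 42 at the full specification).
        """
        return 1 + 2 * self.n_resblocks_per_branch + 1

    @property
    def receptive_field_px(self) -> int:
        """Stacked-conv receptive field, 2*n_convs + 1 pixels."""
        return 2 * self.forward_conv_count + 1

    def receptive_field_um(self, object_sampling_um: float = 4.15) -> float:
        return self.receptive_field_px * object_sampling_um


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters.

    Defaults are CPU-scale; ``full()`` restores the full-scale protocol
    (500 pairs, 224-px patches, batch 12).  ``target`` selects the loss
    target: the continuous binned intensity clipped to [0, 1] (default) or
    binarised occupancy.
    """

    epochs: int = 30
    split: float = 0.8
    patch_px: int = 64
    batch: int = 4
    steps_per_epoch: int | None = None  # default: one pass over the train split
    lr: float = 1e-3
    schedule_period: int = 30
    seed: int = 0
    online_noise: bool = True
    sbr_range: tuple[float, float] = (1.1, 3.0)
    target: str = "continuous"  # {"continuous", "binarized"}
    mixed_precision: bool = False  # stores batches as float32; optional

    def __post_init__(self) -> None:
        if not (0 < self.split < 1):
            raise ValueError("split must be in (0, 1)")
        if self.target not in ("continuous", "binarized"):
            raise ValueError("target must be 'continuous' or 'binarized'")

    @classmethod
    def full(cls) -> "TrainConfig":
        return cls(epochs=30, patch_px=224, batch=12)


@dataclass
class NormStats:
    """Per-channel dataset mean/std for variance stabilisation (floored std)."""

    views_mean: np.ndarray
    views_std: np.ndarray
    refocus_mean: np.ndarray
    refocus_std: np.ndarray

    def to_json(self) -> str:
        return json.dumps({k: np.asarray(v).tolist()
                           for k, v in dataclasses.asdict(self).items()})

    @classmethod
    def from_json(cls, s: str) -> "NormStats":
        d = json.loads(s)
        return cls(**{k: np.asarray(v, float) for k, v in d.items()})


class _ResBlock:
    def __init__(self, width: int, use_bn: bool, rng: np.random.Generator,
                 name: str) -> None:
        self.conv1 = Conv3x3(width, width, rng, f"{name}.conv1")
        self.conv2 = Conv3x3(width, width, rng, f"{name}.conv2")
        self.use_bn = use_bn
        if use_bn:
            self.bn1 = BatchNorm2d(width, name=f"{name}.bn1")
            self.bn2 = BatchNorm2d(width, name=f"{name}.bn2")
        self._mask: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        ps = self.conv1.parameters() + self.conv2.parameters()
        if self.use_bn:
            ps += self.bn1.parameters() + self.bn2.parameters()
        return ps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x, cache=train)
        if self.use_bn:
            h = self.bn1.forward(h, train)
        mask = h > 0
        h = h * mask
        if train:
            self._mask = mask
        h = self.conv2.forward(h, cache=train)
        if self.use_bn:
            h = self.bn2.forward(h, train)
        return x + h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.bn2.backward(dy) if self.use_bn else dy
        d = self.conv2.backward(d)
        d = d * self._mask
        if self.use_bn:
            d = self.bn1.backward(d)
        d = self.conv1.backward(d)
        self._mask = None
        return dy + d


class _Branch:
    def __init__(self, c_in: int, width: int, n_blocks: int, use_bn: bool,
                 rng: np.random.Generator, name: str) -> None:
        self.expand = Conv3x3(c_in, width, rng, f"{name}.expand")
        self.blocks = [_ResBlock(width, use_bn, rng, f"{name}.rb{i}")
                       for i in range(n_blocks)]

    def parameters(self) -> list[Parameter]:
        ps = self.expand.parameters()
        for b in self.blocks:
            ps += b.parameters()
        return ps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x0 = self.expand.forward(x, cache=train)
        h = x0
        for b in self.blocks:
            h = b.forward(h, train)
        return x0 + h  # long skip: first-block input to last-block output

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = dy
        for b in reversed(self.blocks):
            d = b.backward(d)
        return self.expand.backward(d + dy)


class SBRNet:
    """Dual-branch residual network; see the module docstring."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.branch_views = _Branch(spec.in_channels_views, spec.width_channels,
                                    spec.n_resblocks_per_branch,
                                    spec.use_batchnorm, rng, "views")
        self.branch_refocus = _Branch(spec.in_channels_refocus,
                                      spec.width_channels,
                                      spec.n_resblocks_per_branch,
                                      spec.use_batchnorm, rng, "refocus")
        self.final = Conv3x3(spec.width_channels, spec.out_channels, rng, "final")
        # keep the sigmoid unsaturated at the start: the output layer starts
        # near zero logits so cross-entropy gradients reach both classes
        self.final.weight.value *= 0.1

    def parameters(self) -> list[Parameter]:
        return (self.branch_views.parameters()
                + self.branch_refocus.parameters() + self.final.parameters())

    def batchnorms(self) -> list[BatchNorm2d]:
        bns: list[BatchNorm2d] = []
        if not self.spec.use_batchnorm:
            return bns
        for br in (self.branch_views, self.branch_refocus):
            for b in br.blocks:
                bns += [b.bn1, b.bn2]
        return bns

    def forward(self, views: np.ndarray, refocused: np.ndarray,
                train: bool = False) -> np.ndarray:
        """Forward pass; inputs [B, 9, h, w] and [B, 24, h, w] -> [B, 24, h, w]."""
        fused = (self.branch_views.forward(views, train)
                 + self.branch_refocus.forward(refocused, train))
        self._logits = self.final.forward(fused, cache=train)
        return sigmoid(self._logits)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        self.branch_views.backward(d)
        self.branch_refocus.backward(d)

    def count_forward_convs(self) -> int:
        """Walk one branch's graph and count 3x3 convolutions to the output."""
        n = 1  # expansion
        for block in self.branch_views.blocks:
            n += sum(isinstance(c, Conv3x3) for c in (block.conv1, block.conv2))
        return n + 1  # final fusion conv

    # -- state ---------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.value for p in self.parameters()]
        for bn in self.batchnorms():
            arrs += [bn.running_mean, bn.running_var]
        return arrs

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def load_snapshot(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("snapshot does not match the architecture")
        for dst, src in zip(own, arrays):
            dst[...] = src


def build_network(spec: NetworkSpec, seed: int = 0) -> SBRNet:
    """Construct the dual-branch network from its specification."""
    return SBRNet(spec, seed=seed)


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross-entropy, -mean[y log yh + (1-y) log(1-yh)].

    Targets must lie in [0, 1]; predictions are clamped to
    [1e-7, 1 - 1e-7] before the logarithms.
    """
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("targets must lie in [0, 1]")
    if np.any(y_hat < 0) or np.any(y_hat > 1):
        raise ValueError("predictions must lie in [0, 1]")
    yh = np.clip(y_hat, EPS_CLAMP, 1.0 - EPS_CLAMP)
    return float(-(y * np.log(yh) + (1.0 - y) * np.log1p(-yh)).mean())


def compute_normalization_stats(dataset: list[dict]) -> NormStats:
    """Per-channel mean/std over a training set (std floored at 1e-6)."""
    views = np.stack([d["views"] for d in dataset])
    refoc = np.stack([d["refocused"] for d in dataset])
    return NormStats(
        views_mean=views.mean(axis=(0, 2, 3)),
        views_std=np.maximum(views.std(axis=(0, 2, 3)), 1e-6),
        refocus_mean=refoc.mean(axis=(0, 2, 3)),
        refocus_std=np.maximum(refoc.std(axis=(0, 2, 3)), 1e-6),
    )


def variance_stabilize(views: np.ndarray, refocused: np.ndarray,
                       stats: NormStats | None) -> tuple[np.ndarray, np.ndarray]:
    """Standardise each channel with the stored dataset statistics.

    The same statistics must be applied at training and inference; passing
    ``None`` raises, guarding against un-stabilised inference.
    """
    if stats is None:
        raise ValueError("normalization statistics missing (compute them on "
                         "the training split first)")
    v = (views - stats.views_mean[:, None, None]) / stats.views_std[:, None, None]
    r = ((refocused - stats.refocus_mean[:, None, None])
         / stats.refocus_std[:, None, None])
    return v, r


def _loss_target(gt: np.ndarray, mode: str) -> np.ndarray:
    if mode == "binarized":
        return (gt > 0).astype(np.float64)
    return np.clip(gt, 0.0, 1.0)


def train(model: SBRNet, dataset: list[dict], config: TrainConfig,
          noise: NoiseParams | None = None) -> tuple[SBRNet, dict]:
    """Train the network; returns the best-validation model and a history.

    Each dataset entry holds noiseless ``views`` [9,h,w], ``refocused``
    [24,h,w] and ``gt`` [24,h,w].  Per step a random patch is cut from each
    sample, online randomised mixed Poisson-Gaussian noise is applied to the
    inputs (if ``config.online_noise``; preprocessed-input variants train
    with it off), channels are variance-stabilised, and Adam minimises the
    cross-entropy under a cosine-annealed learning rate.  The checkpoint
    with the best validation loss is restored before returning.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    order = rng.permutation(n)
    n_train = max(int(round(config.split * n)), 1)
    if n_train == n and n > 1:
        n_train = n - 1
    train_idx = order[:n_train]
    val_idx = order[n_train:]

    stats = compute_normalization_stats([dataset[i] for i in train_idx])
    noise = noise or NoiseParams()
    opt = Adam(model.parameters(), lr=config.lr)
    dtype = np.float32 if config.mixed_precision else np.float64

    h, w = dataset[0]["views"].shape[1:]
    patch = min(config.patch_px, h, w)

    history: dict = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    best = (np.inf, model.snapshot())

    def _make_batch(indices: np.ndarray, train_mode: bool):
        vs, rs, gs = [], [], []
        for i in indices:
            d = dataset[i]
            r0 = rng.integers(0, h - patch + 1) if train_mode else 0
            c0 = rng.integers(0, w - patch + 1) if train_mode else 0
            sl = np.s_[..., r0:r0 + patch, c0:c0 + patch] if train_mode else np.s_[...]
            v, r, g = d["views"][sl], d["refocused"][sl], d["gt"][sl]
            if train_mode and config.online_noise:
                nv = v.shape[0]
                both = add_mpg_noise(np.concatenate([v, r], axis=0), noise, rng,
                                     randomize=True)
                v, r = both[:nv], both[nv:]
            v, r = variance_stabilize(v, r, stats)
            vs.append(v), rs.append(r), gs.append(_loss_target(g, config.target))
        return (np.stack(vs).astype(dtype), np.stack(rs).astype(dtype),
                np.stack(gs))

    n_steps = config.steps_per_epoch or int(np.ceil(n_train / config.batch))
    for epoch in range(config.epochs):
        lr = cosine_annealing_lr(epoch, config.lr, config.schedule_period)
        perm = np.concatenate([
            rng.permutation(train_idx)
            for _ in range(int(np.ceil(n_steps * config.batch / n_train)))
        ])[:n_steps * config.batch]
        losses = []
        for b0 in range(0, len(perm), config.batch):
            vb, rb, gb = _make_batch(perm[b0:b0 + config.batch], True)
            y = model.forward(vb.astype(np.float64), rb.astype(np.float64),
                              train=True)
            losses.append(bce_loss(gb, y))
            opt.zero_grad()
            model.backward((y - gb) / y.size)  # d(mean BCE)/d(logits)
            opt.step(lr)

        if len(val_idx):
            val_losses = []
            for i in val_idx:
                vb, rb, gb = _make_batch(np.array([i]), False)
                y = model.forward(vb.astype(np.float64), rb.astype(np.float64),
                                  train=False)
                val_losses.append(bce_loss(gb, y))
            val_loss = float(np.mean(val_losses))
        else:
            val_loss = float(np.mean(losses))

        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if val_loss < best[0]:
            best = (val_loss, model.snapshot())

    model.load_snapshot(best[1])
    history["best_val_loss"] = best[0]
    history["stats"] = stats
    return model, history


def reconstruct(model: SBRNet, views: np.ndarray, refocused: np.ndarray,
                stats: NormStats, tile_px: int | None = None,
                overlap_px: int = 16) -> np.ndarray:
    """Inference: full-frame forward pass (or overlap-tiled), output in [0,1].

    With ``tile_px``, tiles of that size with ``overlap_px`` margins are run
    separately and their central regions stitched; away from tile borders
    this matches the full-frame pass.
    """
    if views.ndim != 3 or refocused.ndim != 3:
        raise ValueError("expected [C, h, w] inputs")
    if views.shape[1:] != refocused.shape[1:]:
        raise ValueError("view and refocused grids disagree")
    v, r = variance_stabilize(views, refocused, stats)
    h, w = v.shape[1:]
    if tile_px is None or tile_px >= max(h, w):
        return model.forward(v[None], r[None], train=False)[0]

    out = np.zeros((model.spec.out_channels, h, w))
    step = tile_px - 2 * overlap_px
    if step <= 0:
        raise ValueError("tile_px must exceed twice the overlap")
    for r0 in range(0, h, step):
        for c0 in range(0, w, step):
            rlo = min(max(r0 - overlap_px, 0), max(h - tile_px, 0))
            clo = min(max(c0 - overlap_px, 0), max(w - tile_px, 0))
            rhi, chi = min(rlo + tile_px, h), min(clo + tile_px, w)
            y = model.forward(v[None, :, rlo:rhi, clo:chi],
                              r[None, :, rlo:rhi, clo:chi], train=False)[0]
            wr0, wr1 = r0, min(r0 + step, h)
            wc0, wc1 = c0, min(c0 + step, w)
            out[:, wr0:wr1, wc0:wc1] = y[:, wr0 - rlo:wr1 - rlo,
                                         wc0 - clo:wc1 - clo]
    return out


def save_checkpoint(path: str | Path, model: SBRNet, stats: NormStats,
                    seed: int | None = None) -> None:
    """Archive weights + architecture spec + normalisation stats + seed."""
    meta = {
        "spec": dataclasses.asdict(model.spec),
        "stats": json.loads(stats.to_json()),
        "seed": seed,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(str(path), meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path) -> tuple[SBRNet, NormStats, int | None]:
    with np.load(str(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        n = len([k for k in data.files if k.startswith("arr_")])
        arrays = [data[f"arr_{i}"] for i in range(n)]
    spec = NetworkSpec(**meta["spec"])
    model = SBRNet(spec)
    model.load_snapshot(arrays)
    stats = NormStats(**{k: np.asarray(v, float)
                         for k, v in meta["stats"].items()})
    return model, stats, meta.get("seed")
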