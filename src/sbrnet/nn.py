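"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the reconstruction network needs: bias-free 3x3 same-padding
convolutions (im2col), batch normalisation, ReLU, sigmoid, an Adam
optimizer and a cosine-annealing learning-rate schedule.  Everything is
deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "BatchNorm2d", "Parameter", "Adam", "cosine_annealing_lr",
           "relu", "sigmoid"]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv3x3:
    """Bias-free 3x3 convolution with 1-px zero padding (He initialised)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "conv") -> None:
        std = np.sqrt(2.0 / (c_in * 9))
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in, 3, 3)),
                                f"{name}.weight")
        self.c_in, self.c_out = c_in, c_out
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # win: [B, C, H, W, 3, 3] -> [B, H, W, C, 3, 3] -> [B*H*W, C*9]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * 9)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        cols = self._im2col(x)
        y = cols @ self.weight.value.reshape(self.c_out, -1).T
        if cache:
            self._cols, self._in_shape = cols, x.shape
        return y.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cols is None or self._in_shape is None:
            raise RuntimeError("forward(cache=True) must precede backward")
        b, c, h, w = self._in_shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(b * h * w, self.c_out)
        self.weight.grad += (dyf.T @ self._cols).reshape(self.weight.value.shape)
        dcols = dyf @ self.weight.value.reshape(self.c_out, -1)
        dcols = dcols.reshape(b, h, w, c, 3, 3)
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=np.float64)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, 1:h + 1, 1:w + 1]


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("forward(train=True) must precede backward")
        xhat, inv_std = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (inv_std[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_annealing_lr(epoch: int, lr0: float, period: int,
                        lr_min: float = 0.0) -> float:
    """Cosine-annealed learning rate with the given restart period (epochs)."""
    phase = (epoch % period) / period
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * phase))
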