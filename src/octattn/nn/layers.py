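"""Minimal CNN layer zoo with explicit forward/backward passes.

All layers operate on NCHW float arrays and cache whatever the backward pass
needs during ``forward``.  ``backward`` consumes the upstream gradient,
accumulates parameter gradients into ``.grads`` and returns the gradient with
respect to the layer input.  Parameters live in ``.params`` as a name->array
dict; ``.weight_decay`` lists the names the L2 penalty applies to (weights
only — never biases or batch-norm affine parameters).

The three convolution variants the architecture needs are deliberately
restricted:

* :class:`PatchifyConv` — kernel size equals stride (non-overlapping
  patches), which covers both the 4x4/stride-4 stem and the 2x2/stride-2
  downsampling convolution and reduces to a single matmul per image.
* :class:`DepthwiseConv3x3` — per-channel 3x3, stride 1, same-padding.
* :class:`PointwiseConv` / :class:`TransposedConv1x1` — 1x1 channel mixing;
  at kernel 1 and stride 1 the transposed convolution is the adjoint map
  y_o = sum_i w[i, o] x_i + b_o, i.e. channel mixing through the transposed
  weight matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "PatchifyConv",
    "DepthwiseConv3x3",
    "PointwiseConv",
    "TransposedConv1x1",
    "BatchNorm2d",
    "Linear",
    "glorot_uniform",
]


def glorot_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class: parameter/gradient bookkeeping shared by all layers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.weight_decay: tuple[str, ...] = ()

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def num_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())


class PatchifyConv(Layer):
    """Convolution whose kernel equals its stride (non-overlapping patches)."""

    def __init__(self, in_channels: int, out_channels: int, patch: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.patch = patch
        k = patch
        fan_in = in_channels * k * k
        fan_out = out_channels * k * k
        self.params = {
            "weight": glorot_uniform(rng, (out_channels, in_channels, k, k), fan_in, fan_out, dtype),
            "bias": np.zeros(out_channels, dtype=dtype),
        }
        self.weight_decay = ("weight",)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.patch
        if c != self.in_channels:
            raise ValueError(
                f"channel mismatch: input has {c} channels, layer expects {self.in_channels}"
            )
        if h % k or w % k:
            raise ValueError(
                f"spatial dimensions ({h}, {w}) not divisible by patch stride {k}"
            )
        ho, wo = h // k, w // k
        # (N, C, Ho, k, Wo, k) -> (N, Ho, Wo, C*k*k)
        patches = (
            x.reshape(n, c, ho, k, wo, k)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n, ho, wo, c * k * k)
        )
        self._patches = patches
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        y = patches @ wmat.T + self.params["bias"]
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, f, ho, wo = dy.shape
        k = self.patch
        dyt = dy.transpose(0, 2, 3, 1).reshape(-1, f)
        patches = self._patches.reshape(-1, self.in_channels * k * k)
        self.grads["weight"] += (dyt.T @ patches).reshape(self.params["weight"].shape)
        self.grads["bias"] += dyt.sum(axis=0)
        wmat = self.params["weight"].reshape(f, -1)
        dpatch = (dyt @ wmat).reshape(n, ho, wo, self.in_channels, k, k)
        dx = dpatch.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.in_channels, ho * k, wo * k)
        return np.ascontiguousarray(dx)


class DepthwiseConv3x3(Layer):
    """Per-channel 3x3 convolution, stride 1, same-padding (zeros)."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.channels = channels
        self.params = {
            "weight": glorot_uniform(rng, (channels, 3, 3), 9, 9, dtype),
            "bias": np.zeros(channels, dtype=dtype),
        }
        self.weight_decay = ("weight",)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]} channels, layer expects {self.channels}"
            )
        h, w = x.shape[2], x.shape[3]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp, self._hw = xp, (h, w)
        wk = self.params["weight"]
        y = np.empty_like(x)
        y[:] = self.params["bias"][:, None, None]
        # nine shifted multiply-adds beat an im2col einsum at this kernel size
        for i in range(3):
            for j in range(3):
                y += xp[:, :, i:i + h, j:j + w] * wk[:, i, j][:, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        xp = self._xp
        wk = self.params["weight"]
        gw = self.grads["weight"]
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                gw[:, i, j] += np.einsum(
                    "nchw,nchw->c", xp[:, :, i:i + h, j:j + w], dy, optimize=True
                )
                dxp[:, :, i:i + h, j:j + w] += dy * wk[:, i, j][:, None, None]
        self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        return dxp[:, :, 1:-1, 1:-1]


class PointwiseConv(Layer):
    """1x1 convolution mixing channels; y_o = sum_i w[o, i] x_i + b_o."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.params = {
            "weight": glorot_uniform(rng, (out_channels, in_channels), in_channels, out_channels, dtype),
            "bias": np.zeros(out_channels, dtype=dtype),
        }
        self.weight_decay = ("weight",)
        self.zero_grad()

    def _mixing_matrix(self) -> np.ndarray:  # (out, in)
        return self.params["weight"]

    def _mixing_grad(self, g: np.ndarray) -> np.ndarray:
        return g

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"channel mismatch: input has {c} channels, layer expects {self.in_channels}"
            )
        self._x = x
        xm = x.reshape(n, c, h * w)
        y = np.matmul(self._mixing_matrix(), xm)  # (N, out, H*W)
        y = y.reshape(n, self.out_channels, h, w)
        y += self.params["bias"][:, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, f, h, w = dy.shape
        dym = dy.reshape(n, f, h * w)
        xm = self._x.reshape(n, self.in_channels, h * w)
        self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        gmix = np.tensordot(dym, xm, axes=([0, 2], [0, 2]))  # (out, in)
        self.grads["weight"] += self._mixing_grad(gmix)
        dx = np.matmul(self._mixing_matrix().T, dym)
        return dx.reshape(n, self.in_channels, h, w)


class TransposedConv1x1(PointwiseConv):
    """1x1, stride-1 transposed convolution (shape-preserving adjoint mixing).

    The weight is stored in (in, out) orientation as a transposed convolution
    parameterizes it; the applied map is y_o = sum_i w[i, o] x_i + b_o.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        Layer.__init__(self)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.params = {
            "weight": glorot_uniform(rng, (in_channels, out_channels), in_channels, out_channels, dtype),
            "bias": np.zeros(out_channels, dtype=dtype),
        }
        self.weight_decay = ("weight",)
        self.zero_grad()

    def _mixing_matrix(self) -> np.ndarray:
        return self.params["weight"].T

    def _mixing_grad(self, g: np.ndarray) -> np.ndarray:
        return g.T


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine scale/offset.

    Training mode normalizes with mini-batch statistics and updates the
    running statistics as ``running = momentum * running + (1 - momentum) *
    batch``; evaluation mode normalizes with the running statistics.  The
    running mean/variance are state, not learnables, and are excluded from
    parameter counts.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9,
                 dtype=np.float32) -> None:
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]} channels, layer expects {self.channels}"
            )
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(x.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        self._xhat, self._invstd, self._training = xhat, invstd, training
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][:, None, None]
        dxhat = dy * g
        if not self._training:
            return dxhat * invstd[:, None, None]
        n, _, h, w = dy.shape
        m = n * h * w
        s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        return (invstd[:, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class Linear(Layer):
    """Fully connected layer on (N, in) inputs."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.params = {
            "weight": glorot_uniform(rng, (out_features, in_features), in_features, out_features, dtype),
            "bias": np.zeros(out_features, dtype=dtype),
        }
        self.weight_decay = ("weight",)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"feature mismatch: input has {x.shape[1]} features, layer expects {self.in_features}"
            )
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["weight"] += dy.T @ self._x
        self.grads["bias"] += dy.sum(axis=0)
        return dy @ self.params["weight"]
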