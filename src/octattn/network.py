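"""Attention-gated ConvNeXt-style architecture for OCT B-scan classification.

The network is a plain sequential composition of four block types:

* **stem** — a patchify convolution (kernel = stride = 4) followed by batch
  normalization and swish, turning a 224x224x3 image into a 56x56x96 map:
  ``out1 = swish(BN(Conv4x4/4(I)))``.
* **attention block** — the gated residual unit.  With ``d = BN(DW3x3(x))``
  (depthwise, same-padding), two shape-preserving channel mixers form the
  gate ``m = swish(PW1x1(d)) * swish(T1x1(d))`` and the block output is
  ``sigmoid(m) * swish(d) + x``.  Channel count and spatial size are
  preserved, so the residual addition is exact.
* **downsampling block** — a 2x2/stride-2 convolution that halves the
  spatial size and doubles the channel width.
* **output head** — global average pooling, a fully connected layer and a
  softmax over the class scores.

The default schedule is stages of width 96/192/384/768 with two attention
blocks each and a downsample between consecutive stages (none after the
last), i.e. spatial sides 56 -> 56 -> 28 -> 14 -> 7 -> 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn.functional import sigmoid, softmax, swish, swish_grad
from .nn.layers import (
    BatchNorm2d,
    DepthwiseConv3x3,
    Layer,
    Linear,
    PatchifyConv,
    PointwiseConv,
    TransposedConv1x1,
)

__all__ = [
    "StageConfig",
    "NetworkConfig",
    "ParameterBreakdown",
    "StemBlock",
    "AttentionBlock",
    "DownsampleBlock",
    "OutputHead",
    "AttentionGatedNet",
    "build_network",
    "trace_shapes",
    "count_parameters",
]


@dataclass(frozen=True)
class StageConfig:
    """One stage: ``repeats`` attention blocks at width ``filters``."""

    filters: int
    repeats: int = 2
    followed_by_downsample: bool = True

    def __post_init__(self) -> None:
        if self.filters < 1 or self.repeats < 1:
            raise ValueError("stage filters and repeats must be >= 1")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters; defaults reproduce the published schedule."""

    input_side: int = 224
    input_channels: int = 3
    stem_filters: int = 96
    stem_kernel: int = 4
    stem_stride: int = 4
    stages: tuple[StageConfig, ...] = (
        StageConfig(96), StageConfig(192), StageConfig(384),
        StageConfig(768, followed_by_downsample=False),
    )
    num_classes: int = 2

    def __post_init__(self) -> None:
        if self.stem_kernel != self.stem_stride:
            raise ValueError("the stem is a patchify convolution: kernel must equal stride")
        for v in (self.input_side, self.input_channels, self.stem_filters,
                  self.stem_stride, self.num_classes):
            if v < 1:
                raise ValueError("all NetworkConfig sizes must be positive")
        widths = [s.filters for s in self.stages]
        if widths != sorted(widths):
            raise ValueError("stage filters must be non-decreasing")
        trace_shapes(self, _validate_only=True)

    def with_classes(self, num_classes: int) -> "NetworkConfig":
        return replace(self, num_classes=num_classes)


@dataclass
class ParameterBreakdown:
    """Audited learnable-parameter counts, one entry per component."""

    per_component: list[tuple[str, int]]
    total: int

    def __post_init__(self) -> None:
        assert self.total == sum(n for _, n in self.per_component)


def trace_shapes(config: NetworkConfig, _validate_only: bool = False):
    """Analytic shape propagation through the schedule.

    Returns an ordered list of ``(name, spatial_side, channels)`` giving the
    output shape of every block, without building or running the network.
    Raises ``ValueError`` if any stage would need to halve an odd side or the
    stem stride does not divide the input.
    """
    if config.input_side % config.stem_stride:
        raise ValueError(
            f"input side {config.input_side} not divisible by stem stride {config.stem_stride}"
        )
    side = config.input_side // config.stem_stride
    rows = [("stem", side, config.stem_filters)]
    ch = config.stem_filters
    for i, st in enumerate(config.stages, start=1):
        if st.filters != ch:
            raise ValueError(
                f"stage {i} width {st.filters} does not match incoming channels {ch}"
            )
        for j in range(1, st.repeats + 1):
            rows.append((f"stage{i}_block{j}", side, ch))
        if st.followed_by_downsample:
            if side % 2:
                raise ValueError(
                    f"stage {i} output side {side} is odd and cannot be downsampled 2x"
                )
            side //= 2
            ch *= 2
            rows.append((f"down{i}", side, ch))
    if _validate_only:
        return None
    return rows


class StemBlock(Layer):
    """Patchify convolution -> batch norm -> swish."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator, dtype) -> None:
        super().__init__()
        self.conv = PatchifyConv(config.input_channels, config.stem_filters,
                                 config.stem_stride, rng, dtype)
        self.bn = BatchNorm2d(config.stem_filters, dtype=dtype)

    @property
    def children(self) -> dict[str, Layer]:
        return {"conv": self.conv, "bn": self.bn}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = self.bn.forward(self.conv.forward(x, training), training)
        self._z = z
        return swish(z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(dy * swish_grad(self._z)))


class AttentionBlock(Layer):
    """Gated residual unit: ``sigmoid(m) * swish(d) + x`` with a depthwise core.

    ``d = BN(DW3x3(x))``; the gate ``m`` multiplies a pointwise and a
    transposed-1x1 branch, both swish-activated.  All internal maps keep the
    input's shape, so the residual add is well defined for any C, H, W.
    """

    def __init__(self, channels: int, rng: np.random.Generator, dtype) -> None:
        super().__init__()
        self.channels = channels
        self.dw = DepthwiseConv3x3(channels, rng, dtype)
        self.bn = BatchNorm2d(channels, dtype=dtype)
        self.pw = PointwiseConv(channels, channels, rng, dtype)
        self.tc = TransposedConv1x1(channels, channels, rng, dtype)

    @property
    def children(self) -> dict[str, Layer]:
        return {"dw": self.dw, "bn": self.bn, "pw": self.pw, "tc": self.tc}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]} channels, block expects {self.channels}"
            )
        d = self.bn.forward(self.dw.forward(x, training), training)
        p = self.pw.forward(d, training)
        t = self.tc.forward(d, training)
        sig_p, sig_t, sig_d = sigmoid(p), sigmoid(t), sigmoid(d)
        sp = p * sig_p          # swish(p)
        st = t * sig_t          # swish(t)
        sd = d * sig_d          # swish(d)
        m = sp * st
        sig_m = sigmoid(m)
        self._cache = (d, p, t, sig_d, sig_p, sig_t, sig_m, sp, st, sd)
        out = sig_m * sd
        out += x
        return out

    @staticmethod
    def _swish_grad_cached(x: np.ndarray, s: np.ndarray) -> np.ndarray:
        # d/dx [x*sigmoid(x)] = s*(1 + x*(1-s)), reusing the cached sigmoid
        g = 1.0 - s
        g *= x
        g += 1.0
        g *= s
        return g

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d, p, t, sig_d, sig_p, sig_t, sig_m, sp, st, sd = self._cache
        dm = sig_m * (1.0 - sig_m)
        dm *= sd
        dm *= dy
        gp = dm * st
        gp *= self._swish_grad_cached(p, sig_p)
        gt = dm * sp
        gt *= self._swish_grad_cached(t, sig_t)
        dd = self.pw.backward(gp)
        dd += self.tc.backward(gt)
        gd = dy * sig_m
        gd *= self._swish_grad_cached(d, sig_d)
        dd += gd
        dx = self.dw.backward(self.bn.backward(dd))
        dx += dy
        return dx


class DownsampleBlock(Layer):
    """2x2 convolution with stride 2: halves the side, widens the channels."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, dtype) -> None:
        super().__init__()
        self.conv = PatchifyConv(in_channels, out_channels, 2, rng, dtype)

    @property
    def children(self) -> dict[str, Layer]:
        return {"conv": self.conv}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.conv.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(dy)


class OutputHead(Layer):
    """Global average pooling -> fully connected -> softmax.

    ``forward`` returns class probabilities; ``forward_logits`` exposes the
    pre-softmax scores for the cross-entropy loss and for Grad-CAM, whose
    class score is the raw logit.  ``backward`` expects the gradient with
    respect to the logits.
    """

    def __init__(self, in_channels: int, num_classes: int,
                 rng: np.random.Generator, dtype) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.fc = Linear(in_channels, num_classes, rng, dtype)

    @property
    def children(self) -> dict[str, Layer]:
        return {"fc": self.fc}

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: feature map has {x.shape[1]} channels, "
                f"head expects {self.in_channels}"
            )
        self._spatial = x.shape[2:]
        pooled = x.mean(axis=(2, 3))
        return self.fc.forward(pooled, training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return softmax(self.forward_logits(x, training), axis=1)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dpooled = self.fc.backward(dlogits)
        h, w = self._spatial
        scale = 1.0 / (h * w)
        return np.broadcast_to(
            (dpooled * scale)[:, :, None, None],
            (dpooled.shape[0], dpooled.shape[1], h, w),
        ).copy()


class AttentionGatedNet:
    """The assembled network: an ordered dict of named blocks.

    Use :func:`build_network` to construct one with seeded initialization.
    """

    def __init__(self, config: NetworkConfig, blocks: dict[str, Layer],
                 dtype=np.float32) -> None:
        self.config = config
        self.blocks = blocks
        self.dtype = dtype
        # Per-channel training-set means, set by the trainer ("zerocenter").
        self.input_mean = np.zeros(config.input_channels, dtype=dtype)

    # -- forward ---------------------------------------------------------
    def preprocess(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        return x - self.input_mean[:, None, None]

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.preprocess(x)
        for name, block in self.blocks.items():
            if name == "head":
                return block.forward_logits(h, training)
            h = block.forward(h, training)
        raise RuntimeError("network has no head block")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return softmax(self.forward_logits(x, training), axis=1)

    def forward_collect(self, x: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Inference forward pass that also returns every block's output."""
        feats: dict[str, np.ndarray] = {}
        h = self.preprocess(x)
        logits = None
        for name, block in self.blocks.items():
            if name == "head":
                logits = block.forward_logits(h, training=False)
            else:
                h = block.forward(h, training=False)
                feats[name] = h
        return logits, feats

    # -- backward --------------------------------------------------------
    def backward(self, dlogits: np.ndarray, stop_after: str | None = None) -> np.ndarray:
        """Backpropagate from the logits; returns the input gradient.

        With ``stop_after=<block name>`` the chain stops once the gradient
        with respect to that block's *output* is available and returns it
        (used by Grad-CAM).
        """
        g = dlogits
        for name, block in reversed(self.blocks.items()):
            if stop_after is not None and name == stop_after:
                return g
            g = block.backward(g)
        return g

    # -- parameter access ------------------------------------------------
    def named_layers(self):
        for bname, block in self.blocks.items():
            children = getattr(block, "children", None)
            if children:
                for lname, layer in children.items():
                    yield f"{bname}.{lname}", layer
            else:
                yield bname, block

    def named_parameters(self):
        for lname, layer in self.named_layers():
            for pname, arr in layer.params.items():
                yield f"{lname}.{pname}", layer, pname, arr

    def zero_grad(self) -> None:
        for _, layer in self.named_layers():
            layer.zero_grad()


def build_network(config: NetworkConfig, seed: int = 0, dtype=np.float32) -> AttentionGatedNet:
    """Build the full network with Glorot-uniform, seed-reproducible weights."""
    trace_shapes(config, _validate_only=True)
    rng = np.random.default_rng(seed)
    blocks: dict[str, Layer] = {}
    blocks["stem"] = StemBlock(config, rng, dtype)
    ch = config.stem_filters
    for i, st in enumerate(config.stages, start=1):
        for j in range(1, st.repeats + 1):
            blocks[f"stage{i}_block{j}"] = AttentionBlock(ch, rng, dtype)
        if st.followed_by_downsample:
            blocks[f"down{i}"] = DownsampleBlock(ch, ch * 2, rng, dtype)
            ch *= 2
    blocks["head"] = OutputHead(ch, config.num_classes, rng, dtype)
    return AttentionGatedNet(config, blocks, dtype)


def count_parameters(network: AttentionGatedNet) -> ParameterBreakdown:
    """Audit every learnable array (conv/FC weights and biases, BN affine).

    Batch-norm running statistics are state, not learnables, and are not
    counted.  The per-component list is ordered as the blocks are.
    """
    per: list[tuple[str, int]] = []
    for bname, block in network.blocks.items():
        per.append((bname, block.num_params() if not hasattr(block, "children")
                    else sum(l.num_params() for l in block.children.values())))
    total = sum(n for _, n in per)
    return ParameterBreakdown(per_component=per, total=total)
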