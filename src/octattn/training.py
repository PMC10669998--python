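"""Training recipe: SGDM with a step learning-rate schedule.

The protocol follows the published options: stochastic gradient descent with
momentum 0.9, initial learning rate 0.01, mini-batch 32, L2 coefficient
1e-4 (weights only — biases and batch-norm affine parameters are excluded),
learning rate multiplied by 0.1 every ``lr_drop_period`` epochs, data
reshuffled every epoch, and an 80:20 stratified train/validation split.
After the final epoch the batch-norm inference statistics are recomputed as
population statistics over the whole training set, so evaluation does not
depend on the momentum-averaged running estimates from early, fast-moving
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn.functional import cross_entropy, softmax
from .network import AttentionGatedNet

__all__ = ["TrainConfig", "TrainResult", "stratified_split", "train", "predict",
           "sgdm_step"]


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol (defaults as published)."""

    initial_lr: float = 0.01
    mini_batch: int = 32
    epochs: int = 50
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10
    l2: float = 1e-4
    momentum: float = 0.9
    val_fraction: float = 0.2
    seed: int = 0
    finalize_bn: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie strictly between 0 and 1")
        if min(self.initial_lr, self.lr_drop_factor, self.momentum + 1e-12) <= 0:
            raise ValueError("rates must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def lr_at_epoch(self, epoch: int) -> float:
        """Step schedule: lr = initial * factor^floor(epoch / period), 0-based."""
        return self.initial_lr * self.lr_drop_factor ** (epoch // self.lr_drop_period)


@dataclass
class TrainResult:
    """Curves and the trained network."""

    iteration_log: pd.DataFrame  # epoch, iteration, lr, loss, batch_accuracy
    val_accuracy: list[float]    # percent, one entry per epoch
    final_val_accuracy: float    # percent
    network: AttentionGatedNet
    epochs_completed: int


def stratified_split(manifest_df: pd.DataFrame, val_fraction: float,
                     seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records per class, ``round(n * val_fraction)`` to validation.

    Rounding is round-half-even (Python's ``round``).  The two frames are
    disjoint, their union is the input, and per-class proportions are
    preserved within rounding.  Reproducible under ``seed``.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    val_parts, train_parts = [], []
    for cls, group in manifest_df.groupby("class", sort=True):
        if len(group) == 0:
            raise ValueError(f"class {cls!r} has no records")
        n_val = round(len(group) * val_fraction)
        perm = rng.permutation(group.index.to_numpy())
        val_parts.append(manifest_df.loc[perm[:n_val]])
        train_parts.append(manifest_df.loc[perm[n_val:]])
    val = pd.concat(val_parts).reset_index(drop=True)
    tr = pd.concat(train_parts).reset_index(drop=True)
    return tr, val


def sgdm_step(network: AttentionGatedNet, velocity: dict[str, np.ndarray],
              lr: float, momentum: float, l2: float) -> None:
    """One momentum update: v <- m*v - lr*(g + l2*w[decayed]); w <- w + v.

    The L2 term applies only to parameters named in each layer's
    ``weight_decay`` tuple (convolution and FC weights).
    """
    for name, layer, pname, arr in network.named_parameters():
        g = layer.grads[pname]
        if l2 > 0 and pname in layer.weight_decay:
            g = g + l2 * arr
        v = velocity.get(name)
        if v is None:
            v = np.zeros_like(arr)
        v = momentum * v - lr * g
        velocity[name] = v
        arr += v


def _accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    return float((np.argmax(logits, axis=1) == labels).mean()) * 100.0


def _eval_accuracy(network: AttentionGatedNet, X: np.ndarray, y: np.ndarray,
                   batch: int) -> float:
    correct = 0
    for i in range(0, len(X), batch):
        logits = network.forward_logits(X[i:i + batch], training=False)
        correct += int((np.argmax(logits, axis=1) == y[i:i + batch]).sum())
    return 100.0 * correct / len(X)


def finalize_batchnorm(network: AttentionGatedNet, X: np.ndarray, batch: int) -> None:
    """Set every BN layer's inference statistics to population statistics.

    Runs the network over ``X`` in training-mode forward passes while
    accumulating exact per-channel mean and variance of each BN input, then
    stores them as the running statistics.
    """
    from .nn.layers import BatchNorm2d

    bns = [layer for _, layer in network.named_layers() if isinstance(layer, BatchNorm2d)]
    stats = {id(b): [0, None, None] for b in bns}  # count, sum, sumsq

    originals = {id(b): b.forward for b in bns}

    def make_hook(bn):
        orig = originals[id(bn)]

        def hooked(x, training=False):
            st = stats[id(bn)]
            st[0] += x.shape[0] * x.shape[2] * x.shape[3]
            s = x.sum(axis=(0, 2, 3), dtype=np.float64)
            sq = np.square(x, dtype=np.float64).sum(axis=(0, 2, 3))
            st[1] = s if st[1] is None else st[1] + s
            st[2] = sq if st[2] is None else st[2] + sq
            return orig(x, training=True)

        return hooked

    for bn in bns:
        bn.forward = make_hook(bn)
    try:
        for i in range(0, len(X), batch):
            network.forward_logits(X[i:i + batch], training=False)
    finally:
        for bn in bns:
            bn.forward = originals[id(bn)]
    for bn in bns:
        count, s, sq = stats[id(bn)]
        mean = s / count
        var = sq / count - mean ** 2
        bn.running_mean = mean.astype(bn.running_mean.dtype)
        bn.running_var = np.maximum(var, 0.0).astype(bn.running_var.dtype)


def train(network: AttentionGatedNet,
          train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray] | None,
          config: TrainConfig,
          verbose: bool = False) -> TrainResult:
    """Minimize softmax cross-entropy + L2 with SGDM.

    ``train_data`` / ``val_data`` are ``(images NCHW float, integer labels)``
    pairs.  Images are zero-centered with per-channel training-set means
    (stored on the network for inference).  Validation accuracy is evaluated
    once per epoch.  Fully deterministic under ``config.seed``.
    """
    X, y = train_data
    if len(X) == 0:
        raise ValueError("training set is empty")
    if config.mini_batch > len(X):
        raise ValueError(
            f"mini_batch {config.mini_batch} exceeds training-set size {len(X)}; "
            "reduce the batch size"
        )
    n_classes = network.config.num_classes
    if int(y.max()) >= n_classes:
        raise ValueError("label outside the network's class range")

    # "zerocenter": per-channel mean over the training set
    network.input_mean = X.mean(axis=(0, 2, 3)).astype(network.dtype)

    rng = np.random.default_rng(config.seed)
    velocity: dict[str, np.ndarray] = {}
    rows = []
    val_acc_per_epoch: list[float] = []
    it = 0
    for epoch in range(config.epochs):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(len(X))
        for b0 in range(0, len(X) - config.mini_batch + 1, config.mini_batch):
            idx = order[b0:b0 + config.mini_batch]
            xb, yb = X[idx], y[idx]
            network.zero_grad()
            logits = network.forward_logits(xb, training=True)
            loss = cross_entropy(logits, yb)
            probs = softmax(logits, axis=1)
            d = probs
            d[np.arange(len(yb)), yb] -= 1.0
            d /= len(yb)
            network.backward(d.astype(network.dtype))
            sgdm_step(network, velocity, lr, config.momentum, config.l2)
            it += 1
            rows.append((epoch, it, lr, loss, _accuracy(logits, yb)))
            if verbose:
                print(f"epoch {epoch + 1}/{config.epochs} iter {it} "
                      f"lr {lr:g} loss {loss:.4f}")
        if val_data is not None and len(val_data[0]) > 0:
            va = _eval_accuracy(network, val_data[0], val_data[1], config.mini_batch)
        else:
            va = float("nan")
        val_acc_per_epoch.append(va)
        if verbose:
            print(f"epoch {epoch + 1}: validation accuracy {va:.2f}%")

    if config.finalize_bn:
        finalize_batchnorm(network, X, config.mini_batch)
        if val_data is not None and len(val_data[0]) > 0:
            val_acc_per_epoch[-1] = _eval_accuracy(
                network, val_data[0], val_data[1], config.mini_batch
            )

    log = pd.DataFrame(rows, columns=["epoch", "iteration", "lr", "loss",
                                      "batch_accuracy"])
    return TrainResult(
        iteration_log=log,
        val_accuracy=val_acc_per_epoch,
        final_val_accuracy=val_acc_per_epoch[-1] if val_acc_per_epoch else float("nan"),
        network=network,
        epochs_completed=config.epochs,
    )


def predict(network: AttentionGatedNet, images: np.ndarray,
            batch: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (argmax, lowest index on ties) and probability rows."""
    probs = []
    for i in range(0, len(images), batch):
        probs.append(network.forward(images[i:i + batch], training=False))
    p = np.concatenate(probs, axis=0)
    return np.argmax(p, axis=1), p
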