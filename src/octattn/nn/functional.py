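"""Elementwise activations and classification losses.

Everything operates on plain NumPy arrays of any shape and preserves dtype.
The swish activation x * sigmoid(x) is the network's only nonlinearity apart
from the sigmoid gate and the softmax head.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "sigmoid",
    "sigmoid_grad",
    "swish",
    "swish_grad",
    "softmax",
    "log_softmax",
    "cross_entropy",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    return expit(np.asarray(x))


def sigmoid_grad(x: np.ndarray) -> np.ndarray:
    s = sigmoid(x)
    return s * (1.0 - s)


def swish(x: np.ndarray) -> np.ndarray:
    """Swish (SiLU) activation: x * sigmoid(x).

    Smooth and non-monotone; its global minimum ~= -0.2785 sits near
    x ~= -1.2785, and swish(x)/x -> 1 as x -> +inf.

    Raises
    ------
    ValueError
        If the input contains NaN or infinity.
    """
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("swish received a non-finite activation input")
    return x * sigmoid(x)


def swish_grad(x: np.ndarray) -> np.ndarray:
    """d/dx [x * sigmoid(x)] = sigmoid(x) + x * sigmoid(x) * (1 - sigmoid(x))."""
    s = sigmoid(x)
    return s + x * s * (1.0 - s)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax along ``axis``; rows sum to 1."""
    z = logits - np.max(logits, axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / np.sum(ez, axis=axis, keepdims=True)


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    return z - np.log(np.sum(np.exp(z), axis=axis, keepdims=True))


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean softmax cross-entropy of integer ``labels`` given ``logits`` (N, K)."""
    lsm = log_softmax(logits, axis=1)
    n = logits.shape[0]
    return float(-lsm[np.arange(n), labels].mean())
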