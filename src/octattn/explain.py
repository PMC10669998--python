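"""Grad-CAM class-activation heatmaps and overlay rendering.

Grad-CAM weights the channels of a chosen spatial feature map by the
spatially averaged gradient of the target class *logit* with respect to
that map, rectifies the weighted sum, upsamples it bilinearly to the input
resolution and normalizes to [0, 1] by the per-image maximum.  The default
target layer is the output of the last attention block — the deepest
feature map that still has spatial extent before global pooling.

Per-image max normalization destroys cross-image comparability of absolute
heatmap values; comparisons across images should use the pre-normalized
maps or rank statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .network import AttentionGatedNet

__all__ = ["Heatmap", "grad_cam", "overlay", "save_panel", "default_target_layer"]


@dataclass
class Heatmap:
    """Per-pixel class-relevance map in [0, 1] at input resolution."""

    values: np.ndarray
    target_class: int
    target_layer: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("heatmap must be a 2-D grid")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("heatmap values must lie in [0, 1]")


def default_target_layer(network: AttentionGatedNet) -> str:
    """Deepest attention-block output (the standard Grad-CAM choice here)."""
    names = [n for n in network.blocks if n.startswith("stage")]
    if not names:
        raise ValueError("network has no attention blocks")
    return names[-1]


def grad_cam(network: AttentionGatedNet, image: np.ndarray,
             target_class: int | str = "auto",
             target_layer: str | None = None) -> Heatmap:
    """Compute a Grad-CAM heatmap for one image (CHW float array).

    ``target_class="auto"`` picks the class with the highest softmax
    probability.  The class score is the raw logit, so the map is invariant
    to constant shifts of the logits.  An all-zero rectified map is returned
    as all zeros rather than being normalized.
    """
    if target_layer is None:
        target_layer = default_target_layer(network)
    if target_layer not in network.blocks or target_layer == "head":
        raise ValueError(
            f"target layer {target_layer!r} does not yield a spatial feature map"
        )
    x = image[None] if image.ndim == 3 else image
    if x.shape[0] != 1:
        raise ValueError("grad_cam explains a single image at a time")

    logits, feats = network.forward_collect(x)
    fmap = feats[target_layer]
    if target_class == "auto":
        cls = int(np.argmax(logits[0]))
    else:
        cls = int(target_class)
        if not 0 <= cls < logits.shape[1]:
            raise ValueError(f"class index {cls} out of range")

    dlogits = np.zeros_like(logits)
    dlogits[0, cls] = 1.0
    grad = network.backward(dlogits, stop_after=target_layer)

    weights = grad[0].mean(axis=(1, 2))               # spatial average per channel
    cam = np.einsum("c,chw->hw", weights, fmap[0])
    cam = np.maximum(cam, 0.0)
    h, w = x.shape[2], x.shape[3]
    cam_img = Image.fromarray(cam.astype(np.float32), mode="F")
    cam = np.asarray(cam_img.resize((w, h), Image.BILINEAR), dtype=np.float64)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(values=cam, target_class=cls, target_layer=target_layer)


def _to_rgb01(image: np.ndarray) -> np.ndarray:
    """Accept HW, CHW or HWC float arrays in [0, 1]; return HWC RGB."""
    if image.ndim == 2:
        return np.repeat(image[:, :, None], 3, axis=2)
    if image.ndim == 3 and image.shape[0] in (1, 3):
        image = np.transpose(image, (1, 2, 0))
    if image.shape[2] == 1:
        image = np.repeat(image, 3, axis=2)
    return image


def overlay(heatmap: Heatmap | np.ndarray, image: np.ndarray,
            colormap: str = "jet", alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend a colormapped heatmap over the image.

    Returns an HWC float RGB array in [0, 1]:
    ``(1 - alpha) * image + alpha * colormap(heatmap)``.  ``alpha=0`` is the
    original image, ``alpha=1`` the pure colormapped heatmap.
    """
    import matplotlib

    hm = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    rgb = _to_rgb01(np.asarray(image, dtype=np.float64))
    if hm.shape != rgb.shape[:2]:
        raise ValueError(
            f"heatmap shape {hm.shape} does not match image shape {rgb.shape[:2]}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    cmap = matplotlib.colormaps[colormap]
    colored = cmap(hm)[:, :, :3]
    return (1.0 - alpha) * rgb + alpha * colored


def save_panel(path, image: np.ndarray, heatmap: Heatmap,
               colormap: str = "jet", alpha: float = 0.5) -> None:
    """Write a side-by-side PNG panel: original | heatmap | overlay."""
    import matplotlib

    rgb = _to_rgb01(np.asarray(image, dtype=np.float64))
    cmap = matplotlib.colormaps[colormap]
    hm_rgb = cmap(heatmap.values)[:, :, :3]
    ov = overlay(heatmap, image, colormap, alpha)
    panel = np.concatenate([rgb, hm_rgb, ov], axis=1)
    Image.fromarray(np.round(panel * 255).astype(np.uint8)).save(path)
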