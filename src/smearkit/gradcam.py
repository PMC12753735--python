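"""Grad-CAM class-discriminative localization for the cell classifier.

The heatmap for a target class is built from the gradients of that
class's pre-softmax score with respect to a convolutional layer's
feature maps: each channel is weighted by its spatially averaged
gradient, the weighted sum is rectified, max-normalized to [0, 1] and
upsampled to the input size.  By construction the map is invariant to
any positive rescaling of the target logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn.layers import Conv2D
from .nn.model import Sequential
from .preprocessing import ResizeSpec, resize_bilinear

__all__ = ["Heatmap", "compute_gradcam", "overlay"]


@dataclass(frozen=True)
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1], input-sized
    target_class: int
    layer_name: str


def _layer_index(model: Sequential, layer_name: str | None) -> int:
    conv_idx = [i for i, l in enumerate(model.layers) if isinstance(l, Conv2D)]
    if not conv_idx:
        raise ValueError("model has no convolutional layers")
    if layer_name is None:
        return conv_idx[-1]  # default: last conv layer
    for i in conv_idx:
        if model.layers[i].name == layer_name:
            return i
    raise ValueError(f"{layer_name!r} is not a convolutional layer of this model")


def compute_gradcam(
    model: Sequential,
    roi: np.ndarray,
    target_class: int,
    layer: str | None = None,
) -> Heatmap:
    """Heatmap of spatial evidence for ``target_class`` in one ROI.

    ``roi`` is a single (H, W, C) unit-scaled crop.  A degenerate
    all-zero gradient yields an all-zero map with a warning.
    """
    roi = np.asarray(roi, dtype=np.float32)
    if roi.ndim != 3:
        raise ValueError(f"expected a single (H,W,C) ROI, got {roi.shape}")
    idx = _layer_index(model, layer)
    target_layer = model.layers[idx]

    # forward with caches (dropout layers are identity outside training)
    x = roi[None]
    acts = None
    for i, l in enumerate(model.layers):
        training = True  # build backward caches
        if hasattr(l, "rate"):
            x = l.forward(x, training=False)  # keep dropout off
        else:
            x = l.forward(x, training=training)
        if i == idx:
            acts = x.copy()  # (1, h, w, c) post-activation feature maps
    probs = x[0]
    n_classes = probs.shape[-1]
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target_class {target_class} outside [0, {n_classes})")

    # backward d(logit_target)/d(feature maps); the softmax head's fused
    # contract takes gradients in logit space
    dy = np.zeros((1, n_classes), dtype=np.float32)
    dy[0, target_class] = 1.0
    for l in reversed(model.layers[idx + 1 :]):
        dy = l.backward(dy)
    d_acts = dy  # (1, h, w, c)

    weights = d_acts.mean(axis=(1, 2))  # spatially averaged gradients
    cam = np.maximum((acts * weights[:, None, None, :]).sum(axis=-1)[0], 0.0)
    peak = cam.max()
    if peak <= 0:
        warnings.warn("zero-gradient Grad-CAM; returning an all-zero map")
        values = np.zeros(roi.shape[:2])
    else:
        cam = cam / peak
        values = np.clip(resize_bilinear(cam, ResizeSpec(*roi.shape[:2])), 0.0, 1.0)
    name = target_layer.name
    return Heatmap(values.astype(np.float64), int(target_class), name)


def overlay(image: np.ndarray, heatmap: Heatmap | np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend a colorized heatmap over the ROI (byte-scale output)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    from matplotlib import colormaps

    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    image = np.asarray(image)
    if image.shape[:2] != values.shape:
        raise ValueError("image and heatmap shapes differ")
    if np.issubdtype(image.dtype, np.floating):
        base = np.clip(image, 0, 1) * 255.0
    else:
        base = image.astype(np.float64)
    if base.ndim == 2:
        base = np.repeat(base[..., None], 3, axis=-1)
    colored = colormaps["jet"](values)[..., :3] * 255.0
    return np.rint((1.0 - alpha) * base + alpha * colored).astype(np.uint8)
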