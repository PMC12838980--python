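"""Grad-CAM and input-gradient saliency for the dual-attention CNN.

Grad-CAM targets the attention-refined feature map F'' (the last tensor
before the classifier): channel weights are the spatial means of the
target-logit gradient, the map is ReLU(sum_c w_c F''_c), bilinearly
upsampled to the input resolution and min–max normalized. A constant raw
map (e.g. when the classifier weights are all zero) degenerates to an
all-zero map with a warning.

The localization harness scores how much CAM mass falls inside the
synthetic generator's ground-truth signal mask — a trained model should
beat the mask's area fraction by a clear margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as sk_resize

from .augmentation import inverse_normalize
from .autodiff import Tensor
from .model import DualAttentionCNN

__all__ = ["CamMap", "grad_cam", "saliency", "overlay", "localization_score"]


@dataclass
class CamMap:
    heatmap: np.ndarray       # HxW in [0,1]
    target_class: int
    layer: str
    raw_constant: bool = False


def _normalize_map(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo < 1e-12:
        warnings.warn("constant activation map; returning all zeros")
        return np.zeros_like(raw), True
    return (raw - lo) / (hi - lo), False


def _forward_with_grad(model: DualAttentionCNN, image: np.ndarray,
                       target_class: int, wrt_input: bool):
    model.eval()
    if image.ndim == 3 and image.shape[2] == 3:   # HWC convenience
        image = image.transpose(2, 0, 1)
    x = Tensor(image[None].astype(np.float32), requires_grad=wrt_input)
    logits, inter = model.forward(x, return_intermediates=True)
    k = logits.shape[1]
    if not 0 <= target_class < k:
        raise ValueError(f"target class {target_class} outside [0,{k})")
    seed = np.zeros_like(logits.data)
    seed[0, target_class] = 1.0
    logits.backward(seed)
    return x, inter


def grad_cam(model: DualAttentionCNN, image: np.ndarray, target_class: int,
             layer: str = "features", method: str = "gradcam") -> CamMap:
    """Class activation map for ``target_class`` on one normalized image.

    ``layer`` may be ``"features"`` (the post-channel-attention map F'',
    the default) or ``"backbone"`` (pre-attention). ``method`` selects the
    channel weighting: ``"gradcam"`` uses the classic spatial-mean
    gradient weights; ``"elementwise"`` sums the gradient-activation
    product per position. The classic weighting is only faithful when the
    head is (near) position-invariant — under the default flatten
    classifier its spatial averaging can cancel opposing gradient signs,
    so localization analyses should prefer ``"elementwise"``.
    """
    if method not in ("gradcam", "elementwise"):
        raise ValueError(f"unknown CAM method {method!r}")
    _, inter = _forward_with_grad(model, image, target_class, wrt_input=False)
    fmap: Tensor = inter[layer]
    if fmap.grad is None:
        warnings.warn("zero gradient at target layer; returning all zeros")
        size = model.config.input_size
        return CamMap(np.zeros((size, size)), target_class, layer, True)
    grads = fmap.grad[0]                       # (C,H,W)
    if method == "elementwise":
        raw = np.maximum((grads * fmap.data[0]).sum(axis=0), 0.0)
    else:
        weights = grads.mean(axis=(1, 2))      # spatial mean per channel
        raw = np.maximum((weights[:, None, None] * fmap.data[0]).sum(axis=0), 0.0)
    size = model.config.input_size
    raw = sk_resize(raw, (size, size), order=1)
    heat, constant = _normalize_map(raw)
    return CamMap(heat, target_class, layer, constant)


def saliency(model: DualAttentionCNN, image: np.ndarray,
             target_class: int) -> np.ndarray:
    """Input-gradient saliency: max-over-channels |d logit / d pixel|."""
    x, _ = _forward_with_grad(model, image, target_class, wrt_input=True)
    if x.grad is None:
        warnings.warn("zero input gradient; returning all zeros")
        size = model.config.input_size
        return np.zeros((size, size))
    sal = np.abs(x.grad[0]).max(axis=0)
    heat, _ = _normalize_map(sal)
    return heat


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.5,
            colormap: str = "viridis", denormalize: bool = True) -> np.ndarray:
    """Alpha-blend a colormapped heatmap on the (de-normalized) image.

    Returns an HxWx3 uint8 array; ``alpha=0`` reproduces the image,
    ``alpha=1`` the pure colormap.
    """
    from matplotlib import colormaps

    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0,1]")
    if image.ndim == 3 and image.shape[0] == 3:   # CHW -> HWC
        image = image.transpose(1, 2, 0)
    if image.shape[:2] != heatmap.shape:
        raise ValueError(f"image {image.shape[:2]} vs heatmap {heatmap.shape}")
    base = inverse_normalize(image) if denormalize else np.asarray(image, float)
    base = np.clip(base, 0.0, 1.0)
    colored = colormaps[colormap](heatmap)[..., :3]
    blend = (1.0 - alpha) * base + alpha * colored
    return np.round(np.clip(blend, 0, 1) * 255).astype(np.uint8)


def localization_score(cam: np.ndarray, mask: np.ndarray) -> dict:
    """Inside/outside CAM statistics against a boolean signal mask."""
    mask = np.asarray(mask, dtype=bool)
    if cam.shape != mask.shape:
        raise ValueError("cam and mask shapes differ")
    inside = float(cam[mask].mean()) if mask.any() else 0.0
    outside = float(cam[~mask].mean()) if (~mask).any() else 0.0
    total = float(cam.sum())
    return {
        "inside_mean": inside,
        "outside_mean": outside,
        "mass_inside_fraction": float(cam[mask].sum() / total) if total > 0 else 0.0,
        "mask_area_fraction": float(mask.mean()),
    }
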