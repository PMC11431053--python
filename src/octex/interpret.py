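"""Per-scale Grad-CAM heatmaps for the fused class prediction.

For a chosen class, the gradient of the fused logit is taken with respect
to each backbone stage's output feature map (before texture encoding, which
destroys spatial layout). Channel weights are the spatial averages of those
gradients; the heatmap is the rectified channel-weighted sum of the feature
maps, max-normalised to [0, 1]. Scale I (56x56) reflects broad context,
scale IV (7x7) the aggregated discriminative evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import matplotlib as _mpl

from .autograd import Tensor
from .network import OCTClassifier

__all__ = ["CAMStack", "grad_cam", "grad_cam_stack", "overlay"]


@dataclass
class CAMStack:
    """Four non-negative heatmaps (56/28/14/7 for a 224 input), each
    max-normalised to [0, 1], for one target class."""

    heatmaps: list[np.ndarray]
    target_class: int


def _cam_from(fmap_data: np.ndarray, grad: np.ndarray | None) -> np.ndarray:
    if grad is None:  # scale not connected to the fused logit (ablated config)
        return np.zeros(fmap_data.shape[2:], dtype=np.float64)
    weights = grad.mean(axis=(2, 3))  # (1, C)
    cam = np.maximum((weights[0][:, None, None] * fmap_data[0]).sum(axis=0), 0.0)
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def grad_cam_stack(model: OCTClassifier, image: np.ndarray, target_class: int) -> CAMStack:
    """Heatmaps at all four scales for one preprocessed (H, W) image."""
    if not 0 <= target_class < model.config.n_classes:
        raise ValueError("target_class out of range")
    model.eval()
    x = Tensor(np.asarray(image, dtype=np.float32)[None, None])
    out = model(x)
    model.zero_grad()
    score = out["fused_logits"][0, target_class]
    score.backward()
    maps = [_cam_from(f.data, f.grad) for f in out["pyramid"]]
    return CAMStack(heatmaps=maps, target_class=target_class)


def grad_cam(model: OCTClassifier, image: np.ndarray, scale_index: int,
             target_class: int) -> np.ndarray:
    """Single-scale heatmap; ``scale_index`` in 0..3 (scale I..IV)."""
    if not 0 <= scale_index <= 3:
        raise ValueError("scale_index must be in 0..3")
    return grad_cam_stack(model, image, target_class).heatmaps[scale_index]


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4,
            colormap: str = "jet") -> np.ndarray:
    """Alpha-blend an upsampled heatmap over a grayscale image.

    Returns an (H, W, 3) uint8 color image of the same spatial size as the
    input; with an all-zero heatmap the output is the grayscale input
    rendered through the coldest colormap entry blend.
    """
    from skimage.transform import resize as _resize

    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    hm = np.clip(np.asarray(heatmap, dtype=np.float64), 0.0, 1.0)
    hm_up = _resize(hm, img.shape, order=1, preserve_range=True, anti_aliasing=False)
    colors = _mpl.colormaps[colormap](hm_up)[..., :3]
    base = np.stack([gray] * 3, axis=-1)
    blended = (1.0 - alpha) * base + alpha * colors
    return np.round(255.0 * np.clip(blended, 0.0, 1.0)).astype(np.uint8)
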