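"""Grad-CAM++ heatmaps over the detector's fused feature maps.

For a detector the explained score is the sum of post-sigmoid confidences of
the above-threshold detections (configurable). Channel weights follow the
Grad-CAM++ closed form: with g the gradient of the score w.r.t. the target
activation A, alpha = g^2 / (2 g^2 + sum_spatial A * g^3) and the channel
weight is sum_spatial alpha * ReLU(g); the map is ReLU(sum_c w_c A_c),
min-max normalized and bilinearly upsampled to image resolution. The default
target layer is the stride-8 neck output, where the smallest plant targets
live.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from maizedet.detector import Detector, _prepare_image
from maizedet.nn import Tensor

__all__ = ["ExplainConfig", "HeatMap", "gradcampp", "overlay"]


@dataclass
class HeatMap:
    """A [0,1] single-channel attention map at image resolution."""

    values: np.ndarray
    layer: str
    score_definition: str

    def __post_init__(self):
        v = self.values
        if v.min() < 0 or v.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")


@dataclass
class ExplainConfig:
    target_layer: str = "neck_p3"     # neck output at stride 8
    conf_threshold: float = 0.25
    colormap: str = "jet"
    opacity: float = 0.5
    eps: float = 1e-8

    def __post_init__(self):
        if not (0.0 <= self.opacity <= 1.0):
            raise ValueError("opacity must lie in [0, 1]")


_LAYER_INDEX = {"neck_p3": 0, "neck_p4": 1, "neck_p5": 2}


def _bilinear_resize(m: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = m.shape
    ys = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    xs = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    fy = np.clip(ys - y0, 0, 1)[:, None]
    fx = np.clip(xs - x0, 0, 1)[None, :]
    return (m[np.ix_(y0, x0)] * (1 - fy) * (1 - fx) + m[np.ix_(y0, x1)] * (1 - fy) * fx +
            m[np.ix_(y1, x0)] * fy * (1 - fx) + m[np.ix_(y1, x1)] * fy * fx)


def gradcampp(model: Detector, image: np.ndarray,
              config: ExplainConfig = ExplainConfig()) -> HeatMap:
    """Compute a Grad-CAM++ heatmap for one image.

    If no detection clears the confidence threshold the map is identically
    zero (with a warning), mirroring a detector that attends to nothing.
    """
    import warnings

    s = model.config.input_size
    x, _ = _prepare_image(image, s)
    model.eval()
    feats = model.backbone(Tensor(x))
    n3, n4, n5 = model.neck(feats)
    target = (n3, n4, n5)[_LAYER_INDEX[config.target_layer]]
    target.retain_grad()
    cls_list, _ = model.head((n3, n4, n5))
    # score: sum of post-sigmoid confidences above threshold
    flat = [c.reshape(c.shape[0], c.shape[1], -1) for c in cls_list]
    from maizedet.nn.tensor import concat
    logits = concat(flat, axis=2)
    probs = logits.sigmoid()
    mask = probs.data >= config.conf_threshold
    if not mask.any():
        warnings.warn("no detection above threshold; returning a zero heatmap")
        zero = np.zeros(x.shape[-2:], dtype=np.float32)
        return HeatMap(zero, config.target_layer, "sum of above-threshold confidences")
    score = (probs * Tensor(mask.astype(np.float32))).sum()
    score.backward()
    A = target.data[0]                      # (C, H, W)
    g = target.grad[0]
    g2, g3 = g * g, g * g * g
    denom = 2.0 * g2 + (A * g3).sum(axis=(1, 2), keepdims=True)
    alpha = np.where(np.abs(denom) > config.eps, g2 / denom, 0.0)
    w_c = (alpha * np.maximum(g, 0)).sum(axis=(1, 2))
    cam = np.maximum((w_c[:, None, None] * A).sum(axis=0), 0.0)
    cam = _bilinear_resize(cam, x.shape[-2], x.shape[-1])
    if cam.max() > 0:  # normalize at image resolution so the peak is exactly 1
        cam = (cam - cam.min()) / (cam.max() - cam.min())
    cam = np.clip(cam, 0.0, 1.0)
    return HeatMap(cam.astype(np.float32), config.target_layer,
                   "sum of above-threshold confidences")


def overlay(image: np.ndarray, heatmap: HeatMap,
            config: ExplainConfig = ExplainConfig()) -> np.ndarray:
    """Alpha-blend the colormapped heatmap over the image (both HWC float)."""
    import matplotlib

    img = np.asarray(image, dtype=np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    hm = heatmap.values
    if hm.shape != img.shape[:2]:
        raise ValueError(f"heatmap {hm.shape} does not match image {img.shape[:2]}")
    colored = matplotlib.colormaps[config.colormap](hm)[..., :3].astype(np.float32)
    a = config.opacity
    return np.clip((1 - a) * img + a * colored, 0, 1)
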