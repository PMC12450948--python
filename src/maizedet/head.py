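"""Detection heads: the baseline decoupled head and the TDADH shared-conv head.

Both heads are anchor-free and emit, per pyramid level, class logits
(num_classes channels) and box-side distributions (4*reg_max channels) for
distribution-focal regression: each box side is a categorical distribution
over ``reg_max`` bins decoded by its softmax expectation.

The TDADH head replaces the per-level decoupled branches with a stack shared
across all three levels: per-level 1x1 projections to a common width, two
shared 3x3 conv+GroupNorm layers whose concatenated outputs form the task
interaction feature, layer attention that decomposes the interaction into
classification and regression features, modulated deformable alignment
(offset + sigmoid mask generated from the interaction) on the regression
branch only, shared 1x1 prediction convs, and one learnable Scale per level
on the regression output.
"""

from __future__ import annotations

import numpy as np

from maizedet.nn import (
    Conv2d, ConvBNAct, GroupNorm, Module, ModuleList, Scale, Sequential,
    SiLU, Tensor,
)
from maizedet.nn import tensor as T

__all__ = [
    "ConvGN", "DecoupledHead", "TDADH", "build_head",
    "dynamic_deform_conv", "dfl_expectation", "dfl_decode", "make_anchor_points",
]


class ConvGN(Module):
    """3x3 (or 1x1) conv + GroupNorm + SiLU, the building block of the head."""

    def __init__(self, cin: int, cout: int, k: int = 3, groups_gn: int = 16, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, bias=False, rng=rng)
        self.gn = GroupNorm(groups_gn, cout)
        self.act = SiLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.gn(self.conv(x)))


def make_anchor_points(sizes: list[tuple[int, int]], strides: list[int]) -> np.ndarray:
    """Cell-center anchor points in pixel units, concatenated over levels -> (A, 2)."""
    pts = []
    for (h, w), s in zip(sizes, strides):
        ys, xs = np.mgrid[0:h, 0:w]
        pts.append(np.stack([(xs.ravel() + 0.5) * s, (ys.ravel() + 0.5) * s], axis=1))
    return np.concatenate(pts, axis=0).astype(np.float32)


def dfl_expectation(logits: Tensor, reg_max: int) -> Tensor:
    """Decode side distances as the expectation of the softmax over bin indices.

    ``logits`` has bin values on its last axis; returns the same shape minus
    that axis, with values in [0, reg_max - 1].
    """
    probs = logits.softmax(axis=-1)
    bins = Tensor(np.arange(reg_max, dtype=np.float32))
    return (probs * bins).sum(axis=-1)


def dfl_decode(side_logits: np.ndarray, stride: int, scale: float,
               anchor_point: tuple[float, float], reg_max: int = 16):
    """Decode one anchor's four side distributions into a pixel corner box.

    ``side_logits`` is (4, reg_max) ordered (left, top, right, bottom). The
    decoded side distance is the softmax expectation over bin indices, scaled
    by the level's learnable Scale and by the stride; distances around the
    anchor point give (x1, y1, x2, y2) in pixels.
    """
    z = side_logits - side_logits.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    dist = (p * np.arange(reg_max)).sum(axis=-1) * scale * stride
    ax, ay = anchor_point
    l, t, r, b = dist
    return (ax - l, ay - t, ax + r, ay + b)


def dynamic_deform_conv(features: Tensor, offsets: Tensor, mask: Tensor,
                        weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Modulated deformable 3x3 convolution via explicit bilinear gathering.

    Each of the 9 kernel taps samples the feature map at its integer grid
    location plus a learned offset (bilinear interpolation; out-of-bounds
    samples contribute zero) and is weighted by its sigmoid-bounded mask
    value. Zero offsets with a unit mask reduce to an ordinary 3x3 conv with
    zero padding. ``offsets`` has 2*9 channels ((dy, dx) per tap), ``mask``
    9 channels.
    """
    b, c, h, w = features.shape
    k2 = 9
    if offsets.shape[1] != 2 * k2:
        raise ValueError(f"offsets need {2*k2} channels, got {offsets.shape[1]}")
    if mask.shape[1] != k2:
        raise ValueError(f"mask needs {k2} channels, got {mask.shape[1]}")
    cout = weight.shape[0]
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float32)
    base = []
    for i in range(3):
        for j in range(3):
            base.append(np.stack([ys + (i - 1), xs + (j - 1)]))
    base = Tensor(np.broadcast_to(np.stack(base), (b, k2, 2, h, w)).copy())
    off = offsets.reshape(b, k2, 2, h, w)
    sy = (base + off)[:, :, 0]
    sx = (base + off)[:, :, 1]
    sampled = T.bilinear_sample(features, sx, sy)            # (B, 9, C, H, W)
    sampled = sampled * mask.reshape(b, k2, 1, h, w)
    stacked = sampled.reshape(b, k2 * c, h, w)
    w_flat = weight.transpose(0, 2, 3, 1).reshape(cout, k2 * c, 1, 1)
    return T.conv2d(stacked, w_flat, bias, stride=1, padding=0)


class DecoupledHead(Module):
    """Baseline decoupled head: separate cls/reg branches per level.

    Branch widths follow the reference detector family: the reg branch width
    is max(16, ch0/4, 4*reg_max) and the cls branch width max(ch0,
    num_classes); each branch is two 3x3 conv blocks plus a 1x1 prediction
    conv, with no sharing across levels.
    """

    def __init__(self, in_channels: tuple[int, int, int], num_classes: int = 1,
                 reg_max: int = 16, rng=None):
        super().__init__()
        self.num_classes = num_classes
        self.reg_max = reg_max
        ch = tuple(in_channels)
        c2 = max(16, ch[0] // 4, 4 * reg_max)
        c3 = max(ch[0], min(num_classes, 100))
        self.reg_branches = ModuleList(
            Sequential(ConvBNAct(c, c2, 3, rng=rng), ConvBNAct(c2, c2, 3, rng=rng),
                       Conv2d(c2, 4 * reg_max, 1, rng=rng))
            for c in ch)
        self.cls_branches = ModuleList(
            Sequential(ConvBNAct(c, c3, 3, rng=rng), ConvBNAct(c3, c3, 3, rng=rng),
                       Conv2d(c3, num_classes, 1, rng=rng))
            for c in ch)
        # prior-aware bias init: few objects per cell, rarer at coarse strides
        for branch, stride in zip(self.cls_branches, (8, 16, 32)):
            branch[-1].bias.data[:] = float(np.log(5.0 / num_classes / (640 / stride) ** 2))
        for branch in self.reg_branches:
            branch[-1].bias.data[:] = 1.0
        self.scales = [None, None, None]  # fixed unit scale

    def forward(self, feats) -> tuple[list[Tensor], list[Tensor]]:
        cls_out = [b(f) for b, f in zip(self.cls_branches, feats)]
        reg_out = [b(f) for b, f in zip(self.reg_branches, feats)]
        return cls_out, reg_out

    def scale_values(self) -> list[float]:
        return [1.0, 1.0, 1.0]


class TDADH(Module):
    """Task-dynamically-aligned detection head with shared convolutions."""

    def __init__(self, in_channels: tuple[int, int, int], num_classes: int = 1,
                 reg_max: int = 16, width: int = 64, gn_groups: int = 16, rng=None):
        super().__init__()
        if width % gn_groups:
            raise ValueError(f"head width {width} not divisible by gn_groups {gn_groups}")
        self.num_classes = num_classes
        self.reg_max = reg_max
        self.width = width
        c = width
        # per-level projection to the shared width (not shared: channel counts differ)
        self.proj = ModuleList(ConvGN(ci, c, 1, gn_groups, rng=rng) for ci in in_channels)
        # the two shared Conv_GN 3x3 layers (one parameter set for all levels)
        self.shared1 = ConvGN(c, c, 3, gn_groups, rng=rng)
        self.shared2 = ConvGN(c, c, 3, gn_groups, rng=rng)
        # offset+mask generator from the interaction feature (2*9 + 9 channels)
        self.offset_mask = Conv2d(2 * c, 27, 1, rng=rng)
        self.offset_mask.weight.data *= 0.1  # start near the plain-conv regime
        # layer-attention generators per task (2 layers in the interaction stack)
        self.cls_att = Sequential(Conv2d(2 * c, 2, 1, rng=rng))
        self.reg_att = Sequential(Conv2d(2 * c, 2, 1, rng=rng))
        # deformable alignment of the regression features
        self.align_weight = Tensor(
            (rng or np.random.default_rng()).normal(0, 0.05, size=(c, c, 3, 3)), requires_grad=True)
        self.align_gn = GroupNorm(gn_groups, c)
        # shared prediction convs and per-level regression scales
        self.conv_cls = Conv2d(c, num_classes, 1, rng=rng)
        # shared across strides: use the middle-stride object prior
        self.conv_cls.bias.data[:] = float(np.log(5.0 / num_classes / (640 / 16) ** 2))
        self.conv_reg = Conv2d(c, 4 * reg_max, 1, rng=rng)
        self.conv_reg.bias.data[:] = 1.0
        self.scales = ModuleList(Scale(1.0) for _ in in_channels)
        self.last_align_shapes: list[tuple] = []  # (Cin*9, Cout, Hout, Wout) per level

    def interaction(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        f1 = self.shared1(x)
        f2 = self.shared2(f1)
        return f1, f2, T.concat([f1, f2], axis=1)

    def task_decompose(self, f1: Tensor, f2: Tensor, inter: Tensor,
                       att: Module) -> Tensor:
        """Layer attention over the 2-layer interaction stack -> task feature."""
        pooled = inter.mean(axis=(2, 3), keepdims=True)
        w = att(pooled).sigmoid()                       # (B, 2, 1, 1)
        return f1 * w[:, 0:1] + f2 * w[:, 1:2]

    def forward_level(self, x: Tensor, level: int) -> tuple[Tensor, Tensor]:
        x = self.proj[level](x)
        f1, f2, inter = self.interaction(x)
        om = self.offset_mask(inter)
        offsets, mask = om[:, :18], om[:, 18:].sigmoid()
        cls_feat = self.task_decompose(f1, f2, inter, self.cls_att)
        reg_feat = self.task_decompose(f1, f2, inter, self.reg_att)
        reg_feat = self.align_gn(
            dynamic_deform_conv(reg_feat, offsets, mask, self.align_weight)).silu()
        h, w = reg_feat.shape[-2:]
        self.last_align_shapes.append((9 * self.width, self.width, h, w))
        cls_logits = self.conv_cls(cls_feat)
        reg_logits = self.conv_reg(reg_feat)
        return cls_logits, reg_logits

    def forward(self, feats) -> tuple[list[Tensor], list[Tensor]]:
        cls_out, reg_out = [], []
        self.last_align_shapes = []
        for i, f in enumerate(feats):
            c, r = self.forward_level(f, i)
            cls_out.append(c)
            reg_out.append(r)
        return cls_out, reg_out

    def scale_values(self) -> list[float]:
        return [float(s.value.data) for s in self.scales]


def build_head(in_channels: tuple[int, int, int], num_classes: int = 1,
               reg_max: int = 16, gn_groups: int = 16, width: int = 64,
               shared: bool = True, rng=None) -> Module:
    """Build a detection head over three pyramid levels.

    ``shared=True`` builds the TDADH shared-convolution head, ``False`` the
    baseline decoupled head.
    """
    if len(in_channels) != 3:
        raise ValueError("head expects exactly 3 pyramid levels")
    if shared:
        return TDADH(in_channels, num_classes, reg_max, width, gn_groups, rng=rng)
    return DecoupledHead(in_channels, num_classes, reg_max, rng=rng)
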