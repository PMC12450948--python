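"""Feature-fusion necks: the baseline PANet and the weighted bidirectional FPN.

The bidirectional neck fuses the three pyramid levels (strides 8/16/32) with
fast normalized fusion: every fusion node carries one learnable raw weight per
input, passed through ReLU and normalized by their sum plus a stabilizer, so
effective coefficients are non-negative and sum to at most 1. Relative to the
baseline PANet it adds the weighted fusion at every merge point and a lateral
skip connection from the middle level's original input to its bottom-up node.

Channel handling follows the baseline pyramid (per-level widths preserved):
1x1 convs align channels along the top-down path, nearest-neighbor x2
upsampling and stride-2 convs resample between levels, and each fusion node
is followed by a C2f aggregation block, so the neck's capacity matches the
path-aggregation baseline while the fusion itself becomes weighted and
bidirectional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from maizedet.backbone import C2f, FeatureMapSpec
from maizedet.nn import ConvBNAct, Module, ModuleList, Tensor, UpsampleNearest2d
from maizedet.nn import tensor as T

__all__ = [
    "BiFPNConfig", "FusionNode", "fast_normalized_fusion",
    "BiFPN", "PANetNeck", "build_neck",
]


def fast_normalized_fusion(inputs: list[Tensor], weights: Tensor,
                           eps: float = 1e-4) -> Tensor:
    """Sum_i ReLU(w_i) * I_i / (eps + Sum_j ReLU(w_j)).

    All inputs must share a shape; one raw weight per input.
    """
    shapes = {tuple(t.shape) for t in inputs}
    if len(shapes) != 1:
        raise ValueError(f"fusion inputs must share a shape, got {sorted(shapes)}")
    if weights.numel() != len(inputs):
        raise ValueError(f"{len(inputs)} inputs but {weights.numel()} weights")
    w = weights.relu()
    denom = w.sum() + eps
    out = inputs[0] * (w[0] / denom)
    for i, t in enumerate(inputs[1:], start=1):
        out = out + t * (w[i] / denom)
    return out


class FusionNode(Module):
    """A weighted-fusion node followed by a C2f aggregation block."""

    def __init__(self, n_inputs: int, channels: int, repeats: int = 1,
                 expansion: float = 0.5, eps: float = 1e-4, rng=None):
        super().__init__()
        self.weights = Tensor(np.ones(n_inputs, dtype=np.float32), requires_grad=True)
        self.eps = eps
        self.conv = C2f(channels, channels, repeats, e=expansion, rng=rng)

    def forward(self, inputs: list[Tensor]) -> Tensor:
        return self.conv(fast_normalized_fusion(inputs, self.weights, self.eps))


@dataclass
class BiFPNConfig:
    """Fusion-node capacity and stabilizer of the bidirectional neck.

    ``repeats``/``expansion`` size the per-node C2f aggregation blocks;
    ``passes`` repeats the whole bidirectional sweep; ``eps`` stabilizes the
    fusion-weight normalization.
    """

    repeats: int | tuple[int, int, int, int] = (1, 1, 1, 4)  # td4, td3, bu4, bu5
    expansion: float = 0.25
    passes: int = 1
    eps: float = 1e-4
    down_groups: int = 4      # group count of the stride-2 downsample convs

    def node_repeats(self) -> tuple[int, int, int, int]:
        r = self.repeats
        return (r, r, r, r) if isinstance(r, int) else tuple(r)


class BiFPN(Module):
    """Three-level bidirectional weighted feature fusion.

    Per pass: top-down (1x1 align + upsample x2 + 2-input weighted fusion),
    then bottom-up (stride-2 conv + weighted fusion) where the middle level
    fuses three inputs — its top-down feature, the downsampled lower level,
    and the lateral skip from its original input.
    """

    def __init__(self, config: BiFPNConfig, input_specs, rng=None):
        super().__init__()
        strides = tuple(s.stride for s in input_specs)
        if strides != (8, 16, 32):
            raise ValueError(f"expected input strides (8, 16, 32), got {strides}")
        self.config = config
        c3, c4, c5 = (s.channels for s in input_specs)
        self.up = UpsampleNearest2d(2)
        n_td4, n_td3, n_bu4, n_bu5 = config.node_repeats()
        e, eps = config.expansion, config.eps
        self.passes = ModuleList()
        for _ in range(config.passes):
            st = Module()
            st.align54 = ConvBNAct(c5, c4, 1, rng=rng)
            st.align43 = ConvBNAct(c4, c3, 1, rng=rng)
            st.td4 = FusionNode(2, c4, n_td4, e, eps, rng=rng)
            st.td3 = FusionNode(2, c3, n_td3, e, eps, rng=rng)
            st.down3 = ConvBNAct(c3, c4, 3, 2, groups=config.down_groups, rng=rng)
            st.down4 = ConvBNAct(c4, c5, 3, 2, groups=config.down_groups, rng=rng)
            st.bu4 = FusionNode(3, c4, n_bu4, e, eps, rng=rng)
            st.bu5 = FusionNode(2, c5, n_bu5, e, eps, rng=rng)
            self.passes.append(st)
        self.out_specs = tuple(FeatureMapSpec(c, s)
                               for c, s in zip((c3, c4, c5), (8, 16, 32)))

    def forward(self, feats) -> tuple[Tensor, Tensor, Tensor]:
        p3, p4, p5 = feats
        for st in self.passes:
            td4 = st.td4([p4, self.up(st.align54(p5))])
            out3 = st.td3([p3, self.up(st.align43(td4))])
            out4 = st.bu4([td4, st.down3(out3), p4])  # last input: lateral skip
            out5 = st.bu5([p5, st.down4(out4)])
            p3, p4, p5 = out3, out4, out5
        return p3, p4, p5


class PANetNeck(Module):
    """Baseline path-aggregation neck: FPN top-down plus a bottom-up path."""

    def __init__(self, input_specs, rng=None):
        super().__init__()
        c3, c4, c5 = (s.channels for s in input_specs)
        self.up = UpsampleNearest2d(2)
        self.c2f_td4 = C2f(c4 + c5, c4, 1, rng=rng)
        self.c2f_td3 = C2f(c3 + c4, c3, 1, rng=rng)
        self.down3 = ConvBNAct(c3, c3, 3, 2, rng=rng)
        self.c2f_bu4 = C2f(c3 + c4, c4, 1, rng=rng)
        self.down4 = ConvBNAct(c4, c4, 3, 2, rng=rng)
        self.c2f_bu5 = C2f(c4 + c5, c5, 1, rng=rng)
        self.out_specs = tuple(FeatureMapSpec(c, s)
                               for c, s in zip((c3, c4, c5), (8, 16, 32)))

    def forward(self, feats) -> tuple[Tensor, Tensor, Tensor]:
        p3, p4, p5 = feats
        td4 = self.c2f_td4(T.concat([self.up(p5), p4], axis=1))
        out3 = self.c2f_td3(T.concat([self.up(td4), p3], axis=1))
        out4 = self.c2f_bu4(T.concat([self.down3(out3), td4], axis=1))
        out5 = self.c2f_bu5(T.concat([self.down4(out4), p5], axis=1))
        return out3, out4, out5


def build_neck(config: BiFPNConfig, input_specs, rng=None) -> BiFPN:
    """Build the bidirectional weighted neck over three stride-8/16/32 inputs."""
    return BiFPN(config, input_specs, rng=rng)
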