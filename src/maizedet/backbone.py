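"""Backbones: the baseline CSP backbone and the reparameterizable HG backbone.

Two families are provided:

* ``CSPBackbone`` — the standard small-detector backbone (stacked conv
  downsamples, split-transform-merge C2f blocks, SPPF), used by the baseline
  detector variant.
* ``RepHGBackbone`` — a lightweight hierarchical backbone built from an
  HGStem, densely aggregating Rep_HGBlocks whose light convolutions are
  multi-branch RepConvs, and depthwise stride-2 downsampling between stages.

The structural-reparameterization algebra lives here as free functions:
batch-norm folding, 1x1 -> 3x3 kernel padding, identity-branch Dirac kernels,
RepConv branch fusion, and whole-model ``reparameterize``. A multi-branch
RepConv (3x3+BN, 1x1+BN, optional BN-only identity, summed before ReLU)
collapses exactly into a single 3x3 convolution for deployment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from maizedet.nn import (
    BatchNorm2d, Conv2d, ConvBNAct, Identity, MaxPool2d, Module, ModuleList,
    ReLU, Sequential, Tensor,
)
from maizedet.nn import tensor as T

__all__ = [
    "ConvBNActSpec", "FeatureMapSpec", "StageSpec", "BackboneConfig",
    "fold_bn_into_conv", "pad_1x1_to_3x3", "identity_to_kernel",
    "fuse_repconv", "reparameterize", "build_backbone", "spec_of",
    "RepConv", "RepHGBlock", "HGStem", "RepHGBackbone",
    "Bottleneck", "C2f", "SPPF", "CSPBackbone",
]


# =====================================================================
# Reparameterization algebra
# =====================================================================

@dataclass
class ConvBNActSpec:
    """Weights of a conv followed by batch norm: the substrate of BN folding.

    ``W`` is (Cout, Cin/groups, K, K); ``b`` may be None (conv without bias,
    the usual case before BN). ``gamma/beta/mean/var`` are the BN per-channel
    scale, shift and running statistics; ``eps`` the stability constant.
    """

    W: np.ndarray
    b: np.ndarray | None
    gamma: np.ndarray
    beta: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    eps: float = 1e-5
    activation: str = "identity"
    stride: int = 1
    padding: int = 0
    groups: int = 1

    def __post_init__(self) -> None:
        c = self.W.shape[0]
        for name in ("gamma", "beta", "mean", "var"):
            arr = getattr(self, name)
            if arr.shape != (c,):
                raise ValueError(f"{name} has {arr.shape}, expected ({c},)")
        if np.any(self.var + self.eps <= 0):
            raise ValueError("var + eps must be positive per channel")


@dataclass(frozen=True)
class FeatureMapSpec:
    """Channel count and stride of one pyramid level."""

    channels: int
    stride: int

    def spatial(self, input_size: int) -> int:
        return -(-input_size // self.stride)  # ceil division


def spec_of(block: ConvBNAct) -> ConvBNActSpec:
    """Extract the ConvBNActSpec of an unfused ConvBNAct module."""
    if block.fused:
        raise ValueError("block already fused; no BN statistics remain")
    conv, bn = block.conv, block.bn
    return ConvBNActSpec(
        W=conv.weight.data,
        b=conv.bias.data if conv.bias is not None else None,
        gamma=bn.gamma.data, beta=bn.beta.data,
        mean=bn.running_mean, var=bn.running_var, eps=bn.eps,
        stride=conv.stride, padding=conv.padding, groups=conv.groups,
    )


def fold_bn_into_conv(spec: ConvBNActSpec) -> tuple[np.ndarray, np.ndarray]:
    """Fold batch-norm statistics into the preceding convolution.

    Returns (W', b') with W' = gamma * W / sqrt(var + eps) broadcast per
    output channel and b' = gamma * (b - mean) / sqrt(var + eps) + beta
    (b = 0 when the conv has no bias), so that
    conv(W', b') == BN(conv(W, b)) in eval mode.
    """
    std = np.sqrt(spec.var + spec.eps)
    scale = spec.gamma / std
    w_fused = spec.W * scale[:, None, None, None]
    b = spec.b if spec.b is not None else np.zeros_like(spec.mean)
    b_fused = scale * (b - spec.mean) + spec.beta
    return w_fused.astype(np.float32), b_fused.astype(np.float32)


def pad_1x1_to_3x3(w1: np.ndarray) -> np.ndarray:
    """Zero-pad a 1x1 kernel to 3x3 (value at the spatial center).

    With padding 1, the padded 3x3 convolution is functionally identical to
    the original 1x1 convolution on any input.
    """
    if w1.shape[-2:] != (1, 1):
        raise ValueError(f"expected a 1x1 kernel, got spatial shape {w1.shape[-2:]}")
    w3 = np.zeros(w1.shape[:-2] + (3, 3), dtype=w1.dtype)
    w3[..., 1, 1] = w1[..., 0, 0]
    return w3


def identity_to_kernel(channels: int, groups: int = 1) -> np.ndarray:
    """Per-channel Dirac 3x3 kernel: convolving with it is the identity map."""
    if channels % groups:
        raise ValueError("channels must be divisible by groups")
    cin_g = channels // groups
    k = np.zeros((channels, cin_g, 3, 3), dtype=np.float32)
    for i in range(channels):
        k[i, i % cin_g, 1, 1] = 1.0
    return k


class RepConv(Module):
    """Multi-branch reparameterizable 3x3 convolution block.

    Training structure: 3x3 conv+BN, 1x1 conv+BN, and (when in/out channels
    and stride allow) a BN-only identity branch, summed before a ReLU.
    ``fuse()`` collapses all branches into one 3x3 conv with bias; forward
    then runs the single branch. Fusion is idempotent.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1, groups: int = 1,
                 act="relu", rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.stride, self.groups = cin, cout, stride, groups
        self.dense = ConvBNAct(cin, cout, 3, stride, 1, groups, act=None, rng=rng)
        self.pointwise = ConvBNAct(cin, cout, 1, stride, 0, groups, act=None, rng=rng)
        self.identity_bn = BatchNorm2d(cin) if (cin == cout and stride == 1) else None
        self.act = ReLU() if act == "relu" else Identity()
        self.fused_conv: Conv2d | None = None

    @property
    def fused(self) -> bool:
        return self.fused_conv is not None

    def forward(self, x: Tensor) -> Tensor:
        if self.fused_conv is not None:
            return self.act(self.fused_conv(x))
        y = self.dense(x) + self.pointwise(x)
        if self.identity_bn is not None:
            y = y + self.identity_bn(x)
        return self.act(y)

    def fuse(self) -> "RepConv":
        if self.fused_conv is not None:
            return self
        w, b = fuse_repconv(self)
        conv = Conv2d(self.cin, self.cout, 3, self.stride, 1, self.groups, bias=True)
        conv.weight.data = w
        conv.bias.data = b
        self.fused_conv = conv
        # drop branch parameters: only (W', b') remain
        self.dense = Identity()
        self.pointwise = Identity()
        self.identity_bn = None
        return self


def fuse_repconv(rep: RepConv) -> tuple[np.ndarray, np.ndarray]:
    """Fuse a RepConv's branches into a single 3x3 kernel and bias.

    Each branch is BN-folded, the 1x1 branch is center-padded to 3x3, the
    identity branch becomes a BN-folded Dirac kernel; kernels and biases sum.
    """
    if rep.fused:
        conv = rep.fused_conv
        return conv.weight.data.copy(), conv.bias.data.copy()
    w3, b3 = fold_bn_into_conv(spec_of(rep.dense))
    w1, b1 = fold_bn_into_conv(spec_of(rep.pointwise))
    w = w3 + pad_1x1_to_3x3(w1)
    b = b3 + b1
    if rep.identity_bn is not None:
        bn = rep.identity_bn
        wi, bi = fold_bn_into_conv(ConvBNActSpec(
            W=identity_to_kernel(rep.cin, rep.groups), b=None,
            gamma=bn.gamma.data, beta=bn.beta.data,
            mean=bn.running_mean, var=bn.running_var, eps=bn.eps,
        ))
        w = w + wi
        b = b + bi
    return w.astype(np.float32), b.astype(np.float32)


def reparameterize(model: Module) -> Module:
    """Fuse every RepConv in the model in place; non-Rep weights untouched.

    Idempotent: already-fused RepConvs are left alone.
    """
    for m in model.modules():
        if isinstance(m, RepConv):
            m.fuse()
    return model


# =====================================================================
# Baseline CSP backbone (the reference small-detector backbone)
# =====================================================================

class Bottleneck(Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True,
                 e: float = 0.5, rng=None):
        super().__init__()
        ch = int(c2 * e)
        self.cv1 = ConvBNAct(c1, ch, 3, rng=rng)
        self.cv2 = ConvBNAct(ch, c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Split-transform-merge block with a growing cross-stage concat."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = False,
                 e: float = 0.5, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvBNAct(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvBNAct((2 + n) * self.c, c2, 1, rng=rng)
        self.m = ModuleList(Bottleneck(self.c, self.c, shortcut, e=1.0, rng=rng)
                            for _ in range(n))

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        parts = [y[:, :self.c], y[:, self.c:]]
        for m in self.m:
            parts.append(m(parts[-1]))
        return self.cv2(T.concat(parts, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained k=5 max pools."""

    def __init__(self, c1: int, c2: int, k: int = 5, rng=None):
        super().__init__()
        ch = c1 // 2
        self.cv1 = ConvBNAct(c1, ch, 1, rng=rng)
        self.cv2 = ConvBNAct(ch * 4, c2, 1, rng=rng)
        self.pool = MaxPool2d(k, 1, k // 2)

    def forward(self, x: Tensor) -> Tensor:
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.pool(y[-1]))
        return self.cv2(T.concat(y, axis=1))


class CSPBackbone(Module):
    """The baseline backbone: conv downsamples + C2f stages + SPPF.

    Width/depth follow the nano scale of the reference one-stage detector:
    channels (16, 32, 64, 128, 256) and C2f repeats (1, 2, 2, 1). Exports
    P3/P4/P5 features at strides 8/16/32.
    """

    def __init__(self, rng=None):
        super().__init__()
        w = (16, 32, 64, 128, 256)
        self.stem = ConvBNAct(3, w[0], 3, 2, rng=rng)
        self.down1 = ConvBNAct(w[0], w[1], 3, 2, rng=rng)
        self.c2f1 = C2f(w[1], w[1], 1, shortcut=True, rng=rng)
        self.down2 = ConvBNAct(w[1], w[2], 3, 2, rng=rng)
        self.c2f2 = C2f(w[2], w[2], 2, shortcut=True, rng=rng)
        self.down3 = ConvBNAct(w[2], w[3], 3, 2, rng=rng)
        self.c2f3 = C2f(w[3], w[3], 2, shortcut=True, rng=rng)
        self.down4 = ConvBNAct(w[3], w[4], 3, 2, rng=rng)
        self.c2f4 = C2f(w[4], w[4], 1, shortcut=True, rng=rng)
        self.sppf = SPPF(w[4], w[4], 5, rng=rng)
        self.out_specs = (FeatureMapSpec(w[2], 8), FeatureMapSpec(w[3], 16),
                          FeatureMapSpec(w[4], 32))

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = self.down1(self.stem(x))
        x = self.c2f1(x)
        p3 = self.c2f2(self.down2(x))
        p4 = self.c2f3(self.down3(p3))
        p5 = self.sppf(self.c2f4(self.down4(p4)))
        return p3, p4, p5


# =====================================================================
# Rep_HG backbone
# =====================================================================

class HGStem(Module):
    """Stem: stride-2 conv, a two-conv branch fused with a max-pool branch,
    then a stride-2 squeeze to the stem output width (overall stride 4)."""

    def __init__(self, cin: int, cm: int, cout: int, rng=None):
        super().__init__()
        self.stem1 = ConvBNAct(cin, cm, 3, 2, act="relu", rng=rng)
        self.stem2a = ConvBNAct(cm, cm // 2, 3, 1, act="relu", rng=rng)
        self.stem2b = ConvBNAct(cm // 2, cm, 3, 1, act="relu", rng=rng)
        self.pool = MaxPool2d(3, 1, 1)
        self.stem3 = ConvBNAct(2 * cm, cm, 3, 2, act="relu", rng=rng)
        self.stem4 = ConvBNAct(cm, cout, 1, 1, act="relu", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem1(x)
        branch = self.stem2b(self.stem2a(x))
        pooled = self.pool(x)
        return self.stem4(self.stem3(T.concat([pooled, branch], axis=1)))


class LearnableAffine(Module):
    """Learnable shunt on the activation branch: scale * x + bias, scale init 1."""

    def __init__(self):
        super().__init__()
        self.scale = Tensor(np.array(1.0, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.array(0.0, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.scale + self.bias


class RepHGBlock(Module):
    """Densely aggregated block whose light convs are RepConvs.

    A chain of ``n_light`` RepConvs runs from the block input; the input and
    every chain output are concatenated and squeezed by a 1x1 conv pair
    (squeeze to cout/2, excite to cout). A residual add is applied when
    shapes allow, and the activation branch carries a learnable affine shunt.
    """

    def __init__(self, cin: int, cm: int, cout: int, n_light: int = 3,
                 residual: bool = True, use_lab: bool = True, rng=None):
        super().__init__()
        self.m = ModuleList()
        ch = cin
        for _ in range(n_light):
            self.m.append(RepConv(ch, cm, rng=rng))
            ch = cm
        concat_ch = cin + n_light * cm
        self.squeeze = ConvBNAct(concat_ch, cout // 2, 1, act="relu", rng=rng)
        self.excite = ConvBNAct(cout // 2, cout, 1, act="relu", rng=rng)
        self.lab = LearnableAffine() if use_lab else Identity()
        self.residual = residual and cin == cout

    def forward(self, x: Tensor) -> Tensor:
        parts = [x]
        y = x
        for m in self.m:
            y = m(y)
            parts.append(y)
        out = self.lab(self.excite(self.squeeze(T.concat(parts, axis=1))))
        return out + x if self.residual else out


@dataclass
class StageSpec:
    """One backbone stage: optional depthwise downsample then stacked blocks."""

    mid_channels: int
    out_channels: int
    n_blocks: int = 1
    n_light: int = 3
    downsample: bool = True


@dataclass
class BackboneConfig:
    """Declarative Rep_HG backbone description (stem + four stages).

    The default widths are the package's canonical calibrated configuration;
    stages 2-4 export pyramid features at strides 8/16/32.
    """

    stem_mid: int = 16
    stem_out: int = 16
    stages: list[StageSpec] = field(default_factory=lambda: [
        StageSpec(12, 32, n_blocks=1, n_light=3, downsample=False),
        StageSpec(16, 64, n_blocks=1, n_light=3, downsample=True),
        StageSpec(40, 128, n_blocks=1, n_light=3, downsample=True),
        StageSpec(116, 256, n_blocks=1, n_light=3, downsample=True),
    ])

    def out_specs(self) -> tuple[FeatureMapSpec, FeatureMapSpec, FeatureMapSpec]:
        chans = [s.out_channels for s in self.stages[-3:]]
        return (FeatureMapSpec(chans[0], 8), FeatureMapSpec(chans[1], 16),
                FeatureMapSpec(chans[2], 32))


class RepHGBackbone(Module):
    """Stem + four stages of RepHGBlocks with depthwise stride-2 downsamples."""

    def __init__(self, config: BackboneConfig | None = None, rng=None):
        super().__init__()
        self.config = config or BackboneConfig()
        cfg = self.config
        if len(cfg.stages) != 4:
            raise ValueError("backbone needs exactly 4 stages")
        self.stem = HGStem(3, cfg.stem_mid, cfg.stem_out, rng=rng)
        self.stages = ModuleList()
        self.downs = ModuleList()
        ch = cfg.stem_out
        for spec in cfg.stages:
            if spec.downsample:
                self.downs.append(ConvBNAct(ch, ch, 3, 2, groups=ch, act=None, rng=rng))
            else:
                self.downs.append(Identity())
            blocks = []
            for bi in range(spec.n_blocks):
                blocks.append(RepHGBlock(ch, spec.mid_channels, spec.out_channels,
                                         spec.n_light, rng=rng))
                ch = spec.out_channels
            self.stages.append(Sequential(*blocks))
        self.out_specs = cfg.out_specs()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = self.stem(x)
        feats = []
        for down, stage in zip(self.downs, self.stages):
            x = stage(down(x))
            feats.append(x)
        return feats[1], feats[2], feats[3]


def build_backbone(config: BackboneConfig | None = None, mode: str = "train",
                   rng=None) -> RepHGBackbone:
    """Build the Rep_HG backbone; ``mode='deploy'`` fuses every RepConv."""
    if mode not in ("train", "deploy"):
        raise ValueError(f"mode must be 'train' or 'deploy', got {mode!r}")
    bb = RepHGBackbone(config, rng=rng)
    if mode == "deploy":
        reparameterize(bb)
    return bb
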