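"""Layer modules: convolution, batch/group normalization, pooling, resampling.

Conventions follow the mainstream detector frameworks: NCHW layout, "same"
padding defaulting to k//2, SiLU as the default activation of conv blocks.
Each Conv2d records the layer shape of its last forward pass so the
complexity profiler can do its per-layer multiply-accumulate accounting
without framework hooks.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from maizedet.nn import tensor as T
from maizedet.nn.tensor import Tensor


class Module:
    """Base class with parameter/buffer traversal and train/eval state."""

    def __init__(self) -> None:
        self.training = True
        self._buffer_names: list[str] = []

    # -- traversal ------------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, child in self._children():
            yield from child.named_modules(f"{prefix}.{name}" if prefix else name)

    def modules(self) -> Iterator["Module"]:
        for _, m in self.named_modules():
            yield m

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield (f"{prefix}.{name}" if prefix else name), value
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}.{name}" if prefix else name)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffer_names:
            yield (f"{prefix}.{name}" if prefix else name), getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}.{name}" if prefix else name)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        setattr(self, name, value)
        self._buffer_names.append(name)

    # -- state ----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return sum(p.numel() for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_p = dict(self.named_parameters())
        own_b = dict(self.named_buffers())
        for k, v in state.items():
            if k in own_p:
                if own_p[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: {own_p[k].data.shape} vs {v.shape}")
                own_p[k].data = np.asarray(v, dtype=np.float32).copy()
            elif k in own_b:
                np.copyto(own_b[k], v)
            else:
                raise KeyError(f"unexpected key {k!r} in state dict")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods: Iterable[Module] = ()):
        super().__init__()
        self._mods: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        setattr(self, str(len(self._mods)), m)
        self._mods.append(m)

    def __iter__(self):
        return iter(self._mods)

    def __len__(self):
        return len(self._mods)

    def __getitem__(self, i):
        return self._mods[i]

    def __setitem__(self, i, m):
        setattr(self, str(i), m)
        self._mods[i] = m


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._mods: list[Module] = []
        for m in mods:
            setattr(self, str(len(self._mods)), m)
            self._mods.append(m)

    def __iter__(self):
        return iter(self._mods)

    def __getitem__(self, i):
        return self._mods[i]

    def forward(self, x: Tensor) -> Tensor:
        for m in self._mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


def _activation(name) -> Module:
    if isinstance(name, Module):
        return name
    return {"relu": ReLU, "silu": SiLU, "sigmoid": Sigmoid,
            "identity": Identity, None: Identity}[name]()


class Conv2d(Module):
    """Raw 2-D convolution. Padding defaults to k//2 ("same" for odd k, stride 1)."""

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = cin // groups * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(cout, cin // groups, k, k)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, size=(cout,)), requires_grad=True) \
            if bias else None
        # profiling: when _profile is a list, every forward appends its layer
        # shape (shared modules therefore record one entry per reuse)
        self._profile: list | None = None

    def forward(self, x: Tensor) -> Tensor:
        out = T.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)
        if self._profile is not None:
            self._profile.append(
                (self.cin, self.cout, self.k, out.shape[-2], out.shape[-1], self.groups))
        return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self._profile: list | None = None

    def forward(self, x: Tensor) -> Tensor:
        if self._profile is not None:
            self._profile.append(x.numel())
        c = self.channels
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            with np.errstate(all="ignore"):
                n = x.numel() / c
                unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
                self.running_mean *= 1 - self.momentum
                self.running_mean += self.momentum * mean.data.reshape(c)
                self.running_var *= 1 - self.momentum
                self.running_var += self.momentum * unbiased
            xhat = (x - mean) / (var + self.eps).sqrt()
        else:
            mean = self.running_mean.reshape(1, c, 1, 1)
            std = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - Tensor(mean)) / Tensor(std)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class GroupNorm(Module):
    """Normalization over channel groups within each sample (batch-independent)."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self._profile: list | None = None

    def forward(self, x: Tensor) -> Tensor:
        if self._profile is not None:
            self._profile.append(x.numel())
        b, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(b, g, c // g * h * w)
        mean = xg.mean(axis=2, keepdims=True)
        var = ((xg - mean) ** 2).mean(axis=2, keepdims=True)
        xhat = ((xg - mean) / (var + self.eps).sqrt()).reshape(b, c, h, w)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ConvBNAct(Module):
    """Conv -> BatchNorm -> activation, the basic block of the whole detector.

    ``fuse()`` folds the batch-norm statistics into the convolution weights and
    bias (deploy form); after fusing, forward runs conv+activation only.
    """

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1, act="silu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = _activation(act)
        self.fused = False

    def forward(self, x: Tensor) -> Tensor:
        if self.fused:
            return self.act(self.conv(x))
        return self.act(self.bn(self.conv(x)))

    def fuse(self) -> "ConvBNAct":
        if self.fused:
            return self
        from maizedet.backbone import fold_bn_into_conv, spec_of  # local: avoid cycle
        w, b = fold_bn_into_conv(spec_of(self))
        conv = Conv2d(self.conv.cin, self.conv.cout, self.conv.k, self.conv.stride,
                      self.conv.padding, self.conv.groups, bias=True)
        conv.weight.data = w
        conv.bias.data = b
        self.conv = conv
        self.bn = Identity()
        self.fused = True
        return self


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x: Tensor) -> Tensor:
        return T.max_pool2d(x, self.kernel, self.stride, self.padding)


class UpsampleNearest2d(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        return T.upsample_nearest2d(x, self.scale)


class Scale(Module):
    """A single learnable scalar multiplier (per-level regression scaling)."""

    def __init__(self, init: float = 1.0):
        super().__init__()
        self.value = Tensor(np.array(init, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.value
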