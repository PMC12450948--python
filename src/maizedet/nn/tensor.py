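"""Reverse-mode autodiff Tensor over numpy float32 arrays.

The graph is built eagerly: each operation records its parents and a closure
that accumulates gradients into them. ``Tensor.backward()`` runs a topological
sweep. A global ``no_grad()`` context disables graph construction entirely so
inference-time forwards allocate nothing beyond the activations.

Only the operations the detector needs are implemented; convolution uses an
explicit K*K-slice im2col so both forward and backward are BLAS matmuls plus
strided adds (no per-pixel Python loops).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables autograd graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "retains_grad")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()
        self.retains_grad = False

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None] | None) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(p for p in parents if p.requires_grad)

            def _bw():
                backward(out.grad)

            out._backward = _bw
            # keep full parent list alive for closures referencing their data
            out._prev = tuple(parents)
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float32), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None or grad is self.data else grad
        else:
            self.grad = self.grad + grad

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numel(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def retain_grad(self) -> "Tensor":
        self.retains_grad = True
        return self

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def bw(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._make(out_data, (self, other), bw)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g / (2.0 * out_data))

        return Tensor._make(out_data, (self,), bw)

    def atan(self):
        def bw(g):
            self._accum(g / (1.0 + self.data * self.data))

        return Tensor._make(np.arctan(self.data), (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def bw(g):
            self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(out_data, (self,), bw)

    def clip(self, lo: float | None, hi: float | None):
        """Clamp values; gradient is passed only where the input is inside the range."""
        out_data = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            inside &= self.data > lo
        if hi is not None:
            inside &= self.data < hi

        def bw(g):
            self._accum(g * inside)

        return Tensor._make(out_data, (self,), bw)

    def maximum(self, other):
        other = Tensor._coerce(other)
        pick_self = self.data >= other.data
        out_data = np.where(pick_self, self.data, other.data)

        def bw(g):
            self._accum(g * pick_self)
            other._accum(g * ~pick_self)

        return Tensor._make(out_data, (self, other), bw)

    def minimum(self, other):
        other = Tensor._coerce(other)
        pick_self = self.data <= other.data
        out_data = np.where(pick_self, self.data, other.data)

        def bw(g):
            self._accum(g * pick_self)
            other._accum(g * ~pick_self)

        return Tensor._make(out_data, (self, other), bw)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), bw)

    # -- backward driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar backward")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
                # free intermediate grads/graph unless explicitly retained
                if not node.retains_grad and node is not self:
                    node.grad = None
            if node is not self:
                node._backward = None
        self._backward = None


# -- free functions -----------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bw)


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the last two axes symmetrically by `pad`."""
    if pad == 0:
        return x
    out_data = np.pad(x.data, [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)])

    def bw(g):
        x._accum(g[..., pad:-pad, pad:-pad])

    return Tensor._make(out_data, (x,), bw)


def _im2col(xp: np.ndarray, k: int, s: int, hout: int, wout: int) -> np.ndarray:
    """(B,C,Hp,Wp) -> (B, C, k, k, Hout, Wout) by K*K strided slices."""
    b, c = xp.shape[:2]
    cols = np.empty((b, c, k, k, hout, wout), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + s * hout:s, j:j + s * wout:s]
    return cols


def _col2im(gcols: np.ndarray, xp_shape: tuple, k: int, s: int,
            hout: int, wout: int) -> np.ndarray:
    gxp = np.zeros(xp_shape, dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i:i + s * hout:s, j:j + s * wout:s] += gcols[:, :, i, j]
    return gxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel."""
    b, cin, h, w = x.shape
    cout, cin_g, k, _ = weight.shape
    assert cin == cin_g * groups, f"channel mismatch: {cin} vs {cin_g}*{groups}"
    hout = (h + 2 * padding - k) // stride + 1
    wout = (w + 2 * padding - k) // stride + 1
    xp = np.pad(x.data, [(0, 0), (0, 0), (padding, padding), (padding, padding)]) \
        if padding else x.data
    cols = _im2col(xp, k, stride, hout, wout)
    # (B, g, cin_g*k*k, HW) x (g, cout_g, cin_g*k*k)
    cols_m = cols.reshape(b, groups, cin_g * k * k, hout * wout)
    w_m = weight.data.reshape(groups, cout // groups, cin_g * k * k)
    out = np.einsum("gok,bgkl->bgol", w_m, cols_m, optimize=True) \
        if groups > 1 else (w_m[0] @ cols_m[:, 0])[:, None]
    out = out.reshape(b, cout, hout, wout)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g_m = g.reshape(b, groups, cout // groups, hout * wout)
        if weight.requires_grad:
            gw = np.einsum("bgol,bgkl->gok", g_m, cols_m, optimize=True)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("gok,bgol->bgkl", w_m, g_m, optimize=True) \
                if groups > 1 else (w_m[0].T @ g_m[:, 0])[:, None]
            gcols = gcols.reshape(b, cin, k, k, hout, wout)
            gxp = _col2im(gcols, xp.shape, k, stride, hout, wout)
            x._accum(gxp[:, :, padding:padding + h, padding:padding + w]
                     if padding else gxp)

    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = stride or kernel
    b, c, h, w = x.shape
    hout = (h + 2 * padding - kernel) // stride + 1
    wout = (w + 2 * padding - kernel) // stride + 1
    if padding:
        xp = np.full((b, c, h + 2 * padding, w + 2 * padding), -np.inf, dtype=x.data.dtype)
        xp[:, :, padding:padding + h, padding:padding + w] = x.data
    else:
        xp = x.data
    cols = _im2col(xp, kernel, stride, hout, wout)  # (B,C,k,k,Ho,Wo)
    flat = cols.reshape(b, c, kernel * kernel, hout, wout)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[:, :, None], g[:, :, None], axis=2)
        gcols = gflat.reshape(b, c, kernel, kernel, hout, wout)
        gxp = _col2im(gcols, xp.shape, kernel, stride, hout, wout)
        x._accum(gxp[:, :, padding:padding + h, padding:padding + w] if padding else gxp)

    return Tensor._make(out, (x,), bw)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    out_data = x.data.repeat(scale, axis=-2).repeat(scale, axis=-1)

    def bw(g):
        b, c, h, w = x.shape
        self_g = g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5))
        x._accum(self_g)

    return Tensor._make(out_data, (x,), bw)


def bilinear_sample(x: Tensor, sx: Tensor, sy: Tensor) -> Tensor:
    """Sample x (B,C,H,W) at continuous pixel locations (sx, sy) of shape (B,S,H',W').

    Out-of-bounds samples contribute zero. Differentiable with respect to the
    feature map and both coordinate maps; the gradient of the hard zero-padding
    boundary is the bilinear-weight subgradient.
    """
    b, c, h, w = x.shape
    _, s, ho, wo = sx.shape
    x0 = np.floor(sx.data).astype(np.int64)
    y0 = np.floor(sy.data).astype(np.int64)
    fx = sx.data - x0
    fy = sy.data - y0

    out = np.zeros((b, s, c, ho, wo), dtype=np.float32)
    corner_cache = []
    bidx = np.arange(b)[:, None, None, None]
    for dy in (0, 1):
        for dx in (0, 1):
            xi = x0 + dx
            yi = y0 + dy
            valid = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            xi_c = np.clip(xi, 0, w - 1)
            yi_c = np.clip(yi, 0, h - 1)
            wgt = (fx if dx else 1.0 - fx) * (fy if dy else 1.0 - fy) * valid
            vals = x.data[bidx, :, yi_c, xi_c]          # (B,S,Ho,Wo,C)
            vals = np.moveaxis(vals, -1, 2)             # (B,S,C,Ho,Wo)
            out += wgt[:, :, None] * vals
            corner_cache.append((xi_c, yi_c, valid, wgt, vals, dx, dy))

    def bw(g):  # g: (B,S,C,Ho,Wo)
        if x.requires_grad:
            gx_map = np.zeros_like(x.data)
        gsx = np.zeros_like(sx.data) if sx.requires_grad else None
        gsy = np.zeros_like(sy.data) if sy.requires_grad else None
        flat = gx_map.reshape(b, c, h * w) if x.requires_grad else None
        for xi_c, yi_c, valid, wgt, vals, dx, dy in corner_cache:
            if x.requires_grad:
                contrib = g * wgt[:, :, None]           # (B,S,C,Ho,Wo)
                lin = yi_c * w + xi_c                   # (B,S,Ho,Wo)
                np.add.at(
                    flat,
                    (np.arange(b)[:, None, None, None, None],
                     np.arange(c)[None, None, :, None, None],
                     lin[:, :, None, :, :]),
                    contrib,
                )
            gdot = (g * vals).sum(axis=2)               # (B,S,Ho,Wo)
            if gsx is not None:
                dw_dx = (1.0 if dx else -1.0) * (fy if dy else 1.0 - fy) * valid
                gsx += gdot * dw_dx
            if gsy is not None:
                dw_dy = (1.0 if dy else -1.0) * (fx if dx else 1.0 - fx) * valid
                gsy += gdot * dw_dy
        if x.requires_grad:
            x._accum(gx_map)
        if gsx is not None:
            sx._accum(gsx)
        if gsy is not None:
            sy._accum(gsy)

    return Tensor._make(out, (x, sx, sy), bw)
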