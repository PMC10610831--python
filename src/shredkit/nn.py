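"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Supports exactly the operations the detection-network components need:
broadcasting arithmetic, the usual pointwise nonlinearities, reductions,
concatenation, fancy indexing, 2-D convolution (im2col), stride-1 max
pooling with −inf padding, strided max pooling, and nearest ×2 upsampling.
Gradients are accumulated by topological sweep from ``Tensor.backward()``.

This is deliberately minimal — float32, no graph optimization, CPU only —
which is all the desk-scale structural checks and smoke training require.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward: Callable[[Array], None] | None = backward

    # -- graph -------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.grad is None:
                t.grad = np.zeros_like(t.data)
            if not t._parents:
                t.grad += g
                continue
            t.grad += g
            assert t._backward is not None
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: (
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward=lambda g: (
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        return Tensor(
            self.data**p,
            parents=(self,),
            backward=lambda g: ((self, g * p * self.data ** (p - 1)),),
        )

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: ((self, g * out),))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,), backward=lambda g: ((self, g / self.data),))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: ((self, g / (2 * out + 1e-12)),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, parents=(self,), backward=lambda g: ((self, g * out * (1 - out)),))

    def softplus(self):
        out = np.logaddexp(0.0, self.data).astype(np.float32)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, parents=(self,), backward=lambda g: ((self, g * sig),))

    def arctan(self):
        return Tensor(
            np.arctan(self.data),
            parents=(self,),
            backward=lambda g: ((self, g / (1 + self.data**2)),),
        )

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0
        out = np.where(mask, self.data, slope * self.data)
        return Tensor(
            out, parents=(self,), backward=lambda g: ((self, g * np.where(mask, 1.0, slope)),)
        )

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = self.data * sig
        grad_local = sig * (1 + self.data * (1 - sig))
        return Tensor(out, parents=(self,), backward=lambda g: ((self, g * grad_local),))

    def maximum(self, other):
        other = self._lift(other)
        mask = self.data >= other.data
        return Tensor(
            np.maximum(self.data, other.data),
            parents=(self, other),
            backward=lambda g: (
                (self, _unbroadcast(g * mask, self.shape)),
                (other, _unbroadcast(g * ~mask, other.shape)),
            ),
        )

    def minimum(self, other):
        other = self._lift(other)
        mask = self.data <= other.data
        return Tensor(
            np.minimum(self.data, other.data),
            parents=(self, other),
            backward=lambda g: (
                (self, _unbroadcast(g * mask, self.shape)),
                (other, _unbroadcast(g * ~mask, other.shape)),
            ),
        )

    def clamp_min(self, v: float):
        mask = self.data >= v
        return Tensor(
            np.maximum(self.data, v),
            parents=(self,),
            backward=lambda g: ((self, g * mask),),
        )

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None):
        def bwd(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            return ((self, np.broadcast_to(np.expand_dims(g, axis), self.shape).copy()),)

        return Tensor(self.data.sum(axis=axis), parents=(self,), backward=bwd)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        return Tensor(
            self.data.reshape(*shape),
            parents=(self,),
            backward=lambda g: ((self, g.reshape(self.shape)),),
        )

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            parents=(self,),
            backward=lambda g: ((self, g.transpose(inv)),),
        )


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        outs = []
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(o0, o1)
            outs.append((t, g[tuple(sl)]))
        return tuple(outs)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors), backward=bwd)


def stack_scalars(tensors: Sequence[Tensor]) -> Tensor:
    def bwd(g):
        return tuple((t, np.asarray(g[i], dtype=np.float32).reshape(t.shape)) for i, t in enumerate(tensors))

    return Tensor(np.stack([t.data.reshape(()) for t in tensors]), parents=tuple(tensors), backward=bwd)


# ---------------------------------------------------------------------------
# Convolution / pooling
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """NCHW convolution via im2col; weight is (Cout, Cin, kh, kw)."""
    n, c, h, w = x.shape
    cout, cin, kh, kw = weight.shape
    assert cin == c, f"channel mismatch {cin} != {c}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = weight.data.reshape(cout, -1)
    out = cols @ wmat.T
    out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        grad_w = (gmat.T @ cols).reshape(weight.shape)
        grad_cols = gmat @ wmat  # (n*ho*wo, c*kh*kw)
        grad_cols = grad_cols.reshape(n, ho, wo, c, kh, kw)
        grad_xp = np.zeros((n, c, hp, wp), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                grad_xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                    grad_cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        grad_x = grad_xp[:, :, padding : hp - padding or None, padding : wp - padding or None]
        outs = [(x, grad_x), (weight, grad_w)]
        if bias is not None:
            outs.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(outs)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, parents=parents, backward=bwd)


def maxpool2d(x: Tensor, kernel: int, stride: int = 1) -> Tensor:
    """Max pooling; stride 1 uses same-size −inf padding (a running max filter)."""
    n, c, h, w = x.shape
    if stride == 1:
        pad = kernel // 2
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
        ho, wo = h, w
    else:
        pad = 0
        xp = x.data
        ho = (h - kernel) // stride + 1
        wo = (w - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]
    flat = windows.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        grad_xp = np.zeros_like(xp, dtype=np.float32)
        ki, kj = np.unravel_index(idx, (kernel, kernel))
        ii = (np.arange(ho) * stride)[None, None, :, None] + ki
        jj = (np.arange(wo) * stride)[None, None, None, :] + kj
        nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        nn_ = nn_[:, :, None, None]
        cc = cc[:, :, None, None]
        np.add.at(grad_xp, (nn_, cc, ii, jj), g)
        if pad:
            return ((x, grad_xp[:, :, pad:-pad, pad:-pad]),)
        return ((x, grad_xp),)

    return Tensor(out, parents=(x,), backward=bwd)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling."""
    n, c, h, w = x.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(g):
        return ((x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))),)

    return Tensor(out, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Composable parameter container with torch-like recursion."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            params.extend(_collect(v))
        return params

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor):
        return [v] if v.requires_grad else []
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out: list[Tensor] = []
        for item in v:
            out.extend(_collect(item))
        return out
    if isinstance(v, dict):
        out = []
        for item in v.values():
            out.extend(_collect(item))
        return out
    return []


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1, rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        scale = 0.0 if zero_init else math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(cout, cin, kernel, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.padding = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class CBS(Module):
    """Convolution + bias + SiLU activation (the CBS unit of YOLO diagrams).

    Batch normalization is intentionally omitted: at desk scale (batches of a
    few images) batch statistics are noise, and the bias term absorbs the
    affine shift.
    """

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1, rng=None):
        self.conv = Conv2d(cin, cout, kernel, stride, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x).silu()


class Sequential(Module):
    def __init__(self, *blocks: Module):
        self.blocks = list(blocks)

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class Adam:
    """Standard Adam optimizer over a parameter list."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
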