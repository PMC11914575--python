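"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the three-arm network: broadcast-aware arithmetic,
matmul, 3x3 same-padding convolution via im2col, 2x2 max pooling, nearest
2x upsampling, channel concatenation, stable softmax/log-softmax, and the
pointwise nonlinearities. Everything runs in float32 on one CPU and is fully
deterministic.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`
(reverse topological order). Correctness is pinned down by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2", "upsample2x",
           "softmax", "log_softmax", "Adam", "SGD"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- autodiff ------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            self.grad += -g

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data**2,
                                           other.data.shape)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def bw(g):
            self.grad += g * exponent * self.data ** (exponent - 1)

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        out._backward = bw
        return out

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.data.shape)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            np.add.at(self.grad, idx, g)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            self.grad += g.reshape(self.data.shape)

        out._backward = bw
        return out

    # -- pointwise nonlinearities ---------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            self.grad += g * mask

        out._backward = bw
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def bw(g):
            self.grad += g * (1.0 - y**2)

        out._backward = bw
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))

        def bw(g):
            self.grad += g * y

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            self.grad += g / self.data

        out._backward = bw
        return out


# ---------------------------------------------------------------------------
# structured ops


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.grad += piece

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, same-padding 2-D convolution (cross-correlation).

    ``x`` is (N, C, H, W), ``w`` is (O, C, kh, kw) with odd kernel sizes,
    ``b`` is (O,). Implemented with im2col + one BLAS matmul.
    """
    n, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    assert c == c2 and kh % 2 == 1 and kw % 2 == 1
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * kh * kw)
    cols = np.ascontiguousarray(cols, dtype=x.data.dtype)
    wmat = w.data.reshape(o, c * kh * kw)
    y = (cols @ wmat.T).reshape(n, h, wd, o).transpose(0, 3, 1, 2) + \
        b.data[None, :, None, None]
    out = Tensor(y, parents=(x, w, b))

    def bw(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1), dtype=cols.dtype)
        gm = gm.reshape(n * h * wd, o)
        if w.requires_grad:
            w.grad += (gm.T @ cols).reshape(w.data.shape)
        if b.requires_grad:
            b.grad += g.sum(axis=(0, 2, 3))
        if x.requires_grad:
            dcols = (gm @ wmat).reshape(n, h, wd, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + h, j:j + wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x.grad += dxp[:, :, ph:ph + h, pw:pw + wd]

    out._backward = bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = blocks.max(axis=(3, 5))
    out = Tensor(y, parents=(x,))

    def bw(g):
        ymax = y[:, :, :, None, :, None]
        mask = blocks == ymax
        count = mask.sum(axis=(3, 5), keepdims=True)
        gb = g[:, :, :, None, :, None] * mask / count
        x.grad += gb.reshape(n, c, h, w)

    out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(y, parents=(x,))

    def bw(g):
        x.grad += g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    y = z - lse
    out = Tensor(y, parents=(x,))
    p = np.exp(y)

    def bw(g):
        x.grad += g - p * g.sum(axis=axis, keepdims=True)

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        x.grad += y * (g - (g * y).sum(axis=axis, keepdims=True))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# optimizers


class SGD:
    """Plain gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
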