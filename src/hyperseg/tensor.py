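"""Minimal reverse-mode automatic differentiation over numpy arrays.

The grading environment ships no deep-learning framework, so the network,
losses and optimizers in this package run on this small tensor engine.  It
supports exactly the operations the segmentation models need: broadcasting
arithmetic, the elementwise transcendentals used by Poincare-ball geometry,
reductions, shape surgery, 3-D convolution (via ``sliding_window_view`` +
BLAS ``tensordot``), kernel-2/stride-2 transposed convolution, 2x max
pooling and nearest-neighbour upsampling.

Function names mirror numpy (``arctanh``, ``arcsinh``, ``maximum`` ...) so
that geometry code can be written once against an ``xp`` namespace and run
both on raw numpy arrays and on :class:`Tensor` graphs.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "as_tensor", "parameter", "no_grad",
    "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "tanh", "arctanh", "arcsinh", "sqrt", "relu",
    "maximum", "minimum", "where",
    "sum", "mean", "reshape", "moveaxis", "concatenate", "getitem", "pad",
    "conv3d", "conv_transpose3d_2x", "maxpool3d_2x", "upsample3d_2x",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray plus an optional backward closure into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to Tensor.__r*__ instead of building object arrays
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        if isinstance(data, Tensor):
            data = data.data
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):  # numpy scalar: keep its dtype
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, dtype=np.float64) -> Tensor:
    """A leaf tensor that accumulates gradients."""
    return Tensor(np.asarray(data, dtype=dtype), requires_grad=True)


# ---------------------------------------------------------------------------
# graph plumbing
# ---------------------------------------------------------------------------

def _needs_graph(parents: Sequence[Tensor]) -> bool:
    return _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype, copy=True)
    else:
        t.grad += g


def _make(data: np.ndarray, parents: tuple, backward: Callable) -> Tensor:
    if _needs_graph(parents):
        return Tensor(data, requires_grad=True, _parents=parents, _backward=backward)
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

_SCALARS = (int, float, np.integer, np.floating)


def add(a, b) -> Tensor:
    if isinstance(b, _SCALARS):
        a = as_tensor(a)

        def backward(g):
            _accum(a, g)

        return _make(a.data + b, (a,), backward)
    if isinstance(a, _SCALARS):
        return add(b, a)
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out, (a, b), backward)


def sub(a, b) -> Tensor:
    if isinstance(b, _SCALARS):
        a = as_tensor(a)

        def backward(g):
            _accum(a, g)

        return _make(a.data - b, (a,), backward)
    if isinstance(a, _SCALARS):
        b = as_tensor(b)

        def backward(g):
            _accum(b, -g)

        return _make(a - b.data, (b,), backward)
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(out, (a, b), backward)


def mul(a, b) -> Tensor:
    if isinstance(b, _SCALARS):
        a = as_tensor(a)

        def backward(g):
            _accum(a, g * b)

        return _make(a.data * b, (a,), backward)
    if isinstance(a, _SCALARS):
        return mul(b, a)
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), backward)


def div(a, b) -> Tensor:
    if isinstance(b, _SCALARS):
        return mul(a, 1.0 / b)
    if isinstance(a, _SCALARS):
        b = as_tensor(b)

        def backward(g):
            _accum(b, -g * a / (b.data * b.data))

        return _make(a / b.data, (b,), backward)
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out, (a, b), backward)


def neg(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, -g)

    return _make(-a.data, (a,), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1))

    return _make(out, (a,), backward)


# ---------------------------------------------------------------------------
# elementwise transcendentals
# ---------------------------------------------------------------------------

def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def backward(g):
        _accum(a, g * out)

    return _make(out, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out * out))

    return _make(out, (a,), backward)


def arctanh(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, g / (1.0 - a.data * a.data))

    return _make(np.arctanh(a.data), (a,), backward)


def arcsinh(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, g / np.sqrt(1.0 + a.data * a.data))

    return _make(np.arcsinh(a.data), (a,), backward)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = np.sqrt(a.data)

    def backward(g):
        _accum(a, g / (2.0 * out))

    return _make(out, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def maximum(a, b) -> Tensor:
    if isinstance(b, _SCALARS):
        a = as_tensor(a)
        mask = a.data >= b

        def backward(g):
            _accum(a, g * mask)

        return _make(np.where(mask, a.data, np.asarray(b, dtype=a.data.dtype)),
                     (a,), backward)
    a, b = as_tensor(a), as_tensor(b)
    choose_a = a.data >= b.data

    def backward(g):
        _accum(a, _unbroadcast(g * choose_a, a.data.shape))
        _accum(b, _unbroadcast(g * ~choose_a, b.data.shape))

    return _make(np.where(choose_a, a.data, b.data), (a, b), backward)


def minimum(a, b) -> Tensor:
    if isinstance(b, _SCALARS):
        a = as_tensor(a)
        mask = a.data <= b

        def backward(g):
            _accum(a, g * mask)

        return _make(np.where(mask, a.data, np.asarray(b, dtype=a.data.dtype)),
                     (a,), backward)
    a, b = as_tensor(a), as_tensor(b)
    choose_a = a.data <= b.data

    def backward(g):
        _accum(a, _unbroadcast(g * choose_a, a.data.shape))
        _accum(b, _unbroadcast(g * ~choose_a, b.data.shape))

    return _make(np.where(choose_a, a.data, b.data), (a, b), backward)


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond, dtype=bool)

    def backward(g):
        _accum(a, _unbroadcast(g * cond, a.data.shape))
        _accum(b, _unbroadcast(g * ~cond, b.data.shape))

    return _make(np.where(cond, a.data, b.data), (a, b), backward)


# ---------------------------------------------------------------------------
# reductions & shape surgery
# ---------------------------------------------------------------------------

def sum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        _accum(a, np.broadcast_to(g, a.data.shape))

    return _make(out, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in axes]))
    return sum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    orig = a.data.shape

    def backward(g):
        _accum(a, g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


def moveaxis(a, source, destination) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, np.moveaxis(g, destination, source))

    return _make(np.moveaxis(a.data, source, destination), (a,), backward)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        _accum(a, full)

    return _make(a.data[idx], (a,), backward)


def pad(a, pad_width) -> Tensor:
    a = as_tensor(a)
    slices = tuple(slice(lo, lo + s) for (lo, _hi), s in zip(pad_width, a.data.shape))

    def backward(g):
        _accum(a, g[slices])

    return _make(np.pad(a.data, pad_width), (a,), backward)


# ---------------------------------------------------------------------------
# spatial ops (channel-first volumes: (C, D, H, W))
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, w: np.ndarray, padding: int) -> np.ndarray:
    p = padding
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(x, w.shape[2:], axis=(1, 2, 3))
    # win: (Cin, D, H, W, kd, kh, kw)
    return np.tensordot(w, win, axes=((1, 2, 3, 4), (0, 4, 5, 6)))


def conv3d(x, w, b=None, padding: int | None = None) -> Tensor:
    """'Same'-padded 3-D convolution; x (Cin,D,H,W), w (Cout,Cin,kd,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    k = w.data.shape[2]
    if padding is None:
        padding = k // 2
    out = _conv_forward(x.data, w.data, padding)
    parents: tuple = (x, w)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(-1, 1, 1, 1)
        parents = (x, w, b)

    def backward(g):
        p = padding
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if p else x.data
        win = sliding_window_view(xp, w.data.shape[2:], axis=(1, 2, 3))
        gw = np.tensordot(g, win, axes=((1, 2, 3), (1, 2, 3)))
        _accum(w, gw)
        # full correlation of g with the flipped kernel gives dL/dx
        p2 = w.data.shape[2] - 1 - p
        gp = np.pad(g, ((0, 0), (p2, p2), (p2, p2), (p2, p2))) if p2 else g
        gwin = sliding_window_view(gp, w.data.shape[2:], axis=(1, 2, 3))
        wf = w.data[:, :, ::-1, ::-1, ::-1]
        gx = np.tensordot(wf, gwin, axes=((0, 2, 3, 4), (0, 4, 5, 6)))
        _accum(x, gx)
        if b is not None:
            _accum(b, g.sum(axis=(1, 2, 3)))

    return _make(out, parents, backward)


def conv_transpose3d_2x(x, w, b=None) -> Tensor:
    """Transposed conv, kernel 2 / stride 2: doubles each spatial axis.

    x: (Cin, D, H, W); w: (Cin, Cout, 2, 2, 2) -> (Cout, 2D, 2H, 2W).
    """
    x, w = as_tensor(x), as_tensor(w)
    cin, d, h, wd = x.data.shape
    cout = w.data.shape[1]
    t = np.tensordot(w.data, x.data, axes=((0,), (0,)))  # (Cout,2,2,2,D,H,W)
    t = t.transpose(0, 4, 1, 5, 2, 6, 3)                  # (Cout,D,2,H,2,W,2)
    out = t.reshape(cout, 2 * d, 2 * h, 2 * wd)
    parents: tuple = (x, w)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(-1, 1, 1, 1)
        parents = (x, w, b)

    def backward(g):
        gr = g.reshape(cout, d, 2, h, 2, wd, 2).transpose(0, 2, 4, 6, 1, 3, 5)
        # gr: (Cout,2,2,2,D,H,W)
        gx = np.tensordot(w.data, gr, axes=((1, 2, 3, 4), (0, 1, 2, 3)))
        _accum(x, gx)
        gw = np.tensordot(x.data, gr, axes=((1, 2, 3), (4, 5, 6)))
        _accum(w, gw)
        if b is not None:
            _accum(b, g.sum(axis=(1, 2, 3)))

    return _make(out, parents, backward)


def maxpool3d_2x(x) -> Tensor:
    """2x2x2 max pooling; spatial dims must be even."""
    x = as_tensor(x)
    c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool3d_2x needs even spatial dims, got {(d, h, w)}")
    win = (x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
           .transpose(0, 1, 3, 5, 2, 4, 6)
           .reshape(c, d // 2, h // 2, w // 2, 8))
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=g.dtype)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = (gwin.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
              .transpose(0, 1, 4, 2, 5, 3, 6)
              .reshape(c, d, h, w))
        _accum(x, gx)

    return _make(out, (x,), backward)


def upsample3d_2x(x) -> Tensor:
    """Nearest-neighbour 2x upsampling along the three spatial axes."""
    x = as_tensor(x)
    c, d, h, w = x.data.shape
    out = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        gx = g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))
        _accum(x, gx)

    return _make(out, (x,), backward)
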