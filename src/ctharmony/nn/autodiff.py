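"""Reverse-mode autodiff over numpy arrays with higher-order gradients.

Every primitive op returns a :class:`Tensor` whose per-parent backward
closures are written in terms of the same primitives; the reverse pass
therefore constructs a differentiable graph, and :func:`grad` can be
applied to its own output (double backprop).  Only the ops needed by the
harmonizer are provided.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "parents", "backward_fns", "requires_grad")

    def __init__(self, data, parents=(), backward_fns=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self.backward_fns = tuple(backward_fns)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in self.parents)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __radd__(self, other):
        return add(as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __rmul__(self, other):
        return mul(as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __pow__(self, n):
        return power(self, n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


# ------------------------------------------------------------------ core


def _topo(root: Tensor) -> list[Tensor]:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs: list[Tensor], grad_output: Tensor | None = None) -> list[Tensor]:
    """Gradients of a scalar (or seeded) output w.r.t. ``inputs``.

    The returned gradients are Tensors built from differentiable ops, so
    they can themselves be differentiated.
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(_topo(output)):
        g = grads.get(id(node))
        if g is None:
            continue
        for p, fn in zip(node.parents, node.backward_fns):
            if fn is None or not p.requires_grad:
                continue
            contrib = fn(g)
            prev = grads.get(id(p))
            grads[id(p)] = contrib if prev is None else add(prev, contrib)
    return [grads.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]


# ------------------------------------------------------- shape helpers


def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.data.shape == shape:
        return g
    extra = g.data.ndim - len(shape)
    axes = tuple(range(extra)) + tuple(
        i + extra for i, n in enumerate(shape) if n == 1 and g.data.shape[i + extra] != 1
    )
    out = sum_(g, axis=axes, keepdims=True) if axes else g
    return reshape(out, shape)


def broadcast_to(x: Tensor, shape) -> Tensor:
    if x.data.shape == tuple(shape):
        return x
    out = np.broadcast_to(x.data, shape).copy()
    return Tensor(out, (x,), (lambda g: _sum_to(g, x.data.shape),))


def reshape(x: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    if x.data.shape == shape:
        return x
    return Tensor(x.data.reshape(shape), (x,), (lambda g: reshape(g, x.data.shape),))


def transpose(x: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return Tensor(x.data.transpose(axes), (x,), (lambda g: transpose(g, inv),))


# --------------------------------------------------------- arithmetic


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data + b.data,
        (a, b),
        (lambda g: _sum_to(g, a.data.shape), lambda g: _sum_to(g, b.data.shape)),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data - b.data,
        (a, b),
        (lambda g: _sum_to(g, a.data.shape), lambda g: _sum_to(neg(g), b.data.shape)),
    )


def neg(x: Tensor) -> Tensor:
    return Tensor(-x.data, (x,), (lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data * b.data,
        (a, b),
        (lambda g: _sum_to(mul(g, b), a.data.shape), lambda g: _sum_to(mul(g, a), b.data.shape)),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    return mul(a, power(b, -1.0))


def power(x: Tensor, n: float) -> Tensor:
    out = Tensor(x.data**n, (x,), ())
    out.parents = (x,)
    out.backward_fns = (lambda g: mul(g, mul(Tensor(np.array(float(n))), power(x, n - 1.0))),)
    return out


def exp(x: Tensor) -> Tensor:
    out = Tensor(np.exp(x.data), (x,), ())
    out.backward_fns = (lambda g: mul(g, out),)
    return out


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), (x,), (lambda g: div(g, x),))


def sqrt(x: Tensor) -> Tensor:
    return power(x, 0.5)


def abs_(x: Tensor) -> Tensor:
    sign = Tensor(np.sign(x.data))
    return Tensor(np.abs(x.data), (x,), (lambda g: mul(g, sign),))


def tanh(x: Tensor) -> Tensor:
    out = Tensor(np.tanh(x.data), (x,), ())
    out.backward_fns = (lambda g: mul(g, sub(Tensor(np.array(1.0)), mul(out, out))),)
    return out


def relu(x: Tensor) -> Tensor:
    mask = Tensor((x.data > 0).astype(np.float64))
    return Tensor(x.data * mask.data, (x,), (lambda g: mul(g, mask),))


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    factor = Tensor(np.where(x.data > 0, 1.0, slope))
    return Tensor(x.data * factor.data, (x,), (lambda g: mul(g, factor),))


def clip01(x: Tensor) -> Tensor:
    """Ramp activation: clip into [0, 1] (subgradient 0 outside)."""
    mask = Tensor(((x.data > 0) & (x.data < 1)).astype(np.float64))
    return Tensor(np.clip(x.data, 0.0, 1.0), (x,), (lambda g: mul(g, mask),))


# ---------------------------------------------------------- reductions


def sum_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * x.data.ndim), x.data.shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        if keepdims:
            return broadcast_to(g, x.data.shape)
        kshape = list(x.data.shape)
        for a in axes:
            kshape[a] = 1
        return broadcast_to(reshape(g, kshape), x.data.shape)

    return Tensor(data, (x,), (backward,))


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(x, axis=axis, keepdims=keepdims), Tensor(np.array(1.0 / float(n))))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data @ b.data,
        (a, b),
        (
            lambda g: matmul(g, transpose(b, (1, 0))),
            lambda g: matmul(transpose(a, (1, 0)), g),
        ),
    )


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_backward(k):
        def backward(g):
            sl = [slice(None)] * g.data.ndim
            sl[axis] = slice(int(offsets[k]), int(offsets[k + 1]))
            return strided_slice(g, tuple(sl))

        return backward

    return Tensor(data, tuple(tensors), tuple(make_backward(k) for k in range(len(tensors))))


def strided_slice(x: Tensor, slices: tuple) -> Tensor:
    data = x.data[slices]

    def backward(g):
        return scatter(g, slices, x.data.shape)

    return Tensor(data, (x,), (backward,))


def scatter(x: Tensor, slices: tuple, shape: tuple) -> Tensor:
    data = np.zeros(shape)
    data[slices] = x.data
    return Tensor(data, (x,), (lambda g: strided_slice(g, slices),))


def pad2d(x: Tensor, ph: int, pw: int) -> Tensor:
    """Zero-pad the trailing two axes symmetrically."""
    if ph == 0 and pw == 0:
        return x
    width = [(0, 0)] * (x.data.ndim - 2) + [(ph, ph), (pw, pw)]
    data = np.pad(x.data, width)
    sl = (Ellipsis, slice(ph, ph + x.data.shape[-2]), slice(pw, pw + x.data.shape[-1]))
    return Tensor(data, (x,), (lambda g: strided_slice(g, sl),))


def flip2d(x: Tensor) -> Tensor:
    """Reverse the trailing two axes."""
    sl = (Ellipsis, slice(None, None, -1), slice(None, None, -1))
    return Tensor(x.data[sl], (x,), (lambda g: flip2d(g),))


# -------------------------------------------------------- convolution


def _conv2d_valid_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    # x: (B, C, H, W), w: (O, C, kh, kw) -> (B, O, H-kh+1, W-kw+1)
    kh, kw = w.shape[2], w.shape[3]
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return np.einsum("bcyxij,ocij->boyx", windows, w, optimize=True)


def conv2d_valid(x: Tensor, w: Tensor) -> Tensor:
    """Valid cross-correlation; backward passes are themselves conv ops."""
    data = _conv2d_valid_raw(x.data, w.data)
    kh, kw = w.data.shape[2], w.data.shape[3]

    def backward_x(g):
        w_hat = transpose(flip2d(w), (1, 0, 2, 3))  # (C, O, kh, kw)
        return conv2d_valid(pad2d(g, kh - 1, kw - 1), w_hat)

    def backward_w(g):
        x_t = transpose(x, (1, 0, 2, 3))  # (C, B, H, W)
        g_t = transpose(g, (1, 0, 2, 3))  # (O, B, oh, ow)
        return transpose(conv2d_valid(x_t, g_t), (1, 0, 2, 3))

    return Tensor(data, (x, w), (backward_x, backward_w))


def conv2d(x: Tensor, w: Tensor, bias: Tensor | None = None, stride: int = 1, padding: int = 0):
    """Conv over (B, C, H, W) with symmetric zero padding and stride."""
    if padding:
        x = pad2d(x, padding, padding)
    out = conv2d_valid(x, w)
    if stride > 1:
        sl = (slice(None), slice(None), slice(None, None, stride), slice(None, None, stride))
        out = strided_slice(out, sl)
    if bias is not None:
        out = add(out, reshape(bias, (1, -1, 1, 1)))
    return out
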