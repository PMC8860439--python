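"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the frame-classification network needs:
broadcasting add/multiply, 2-D matrix product, sigmoid/tanh/ReLU, basic
indexing, reshape/transpose, stack/concatenate, stride-1 'same' 2-D
convolution, frequency-axis max pooling, and a fused softmax
cross-entropy.  Gradients are accumulated by reverse topological traversal
from a scalar loss.  All gradient formulas are verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "conv2d_same", "maxpool_freq", "softmax_cross_entropy",
           "stack", "concat"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo, seen = [], set()

        def visit(node):
            stack = [(node, iter(node._parents))]
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        seen.add(id(self))
        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- elementwise / linear algebra -------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    def matmul(self, other):
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    def sigmoid(self):
        y = expit(self.data)
        out = Tensor(y, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bwd
        return out

    # ---- shape manipulation -----------------------------------------------

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice, type(None))) for p in parts)

        def bwd(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                if basic:  # basic indexing never selects an element twice
                    buf[idx] += g
                else:
                    np.add.at(buf, idx, g)
                self._accum(buf)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _parents=(self,))
        inverse = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inverse))

        out._backward = bwd
        return out


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def stack(tensors, axis=0):
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))

    def bwd(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(np.squeeze(piece, axis=axis))

    out._backward = bwd
    return out


def concat(tensors, axis=0):
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


# ---- network-specific operations ------------------------------------------


def _im2col_same(x, kh, kw):
    """(B, C, F, T) -> (B, C*kh*kw, F*T) patch matrix, zero 'same' padding."""
    b, c, f, t = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # view: (B, C, F, T, kh, kw) -> (B, C, kh, kw, F, T)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kh * kw, f * t)
    return np.ascontiguousarray(cols)


def _conv2d_same_raw(x, w):
    """Stride-1 cross-correlation with 'same' zero padding (numpy only)."""
    b, c, f, t = x.shape
    cout, cin, kh, kw = w.shape
    assert cin == c
    cols = _im2col_same(x, kh, kw)
    y = (w.reshape(cout, -1) @ cols).reshape(b, cout, f, t)
    return y, cols


def conv2d_same(x: Tensor, w: Tensor, bias: Tensor) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, odd kernel, 'same' pad.

    Input (B, Cin, F, T), filters (Cout, Cin, kh, kw), bias (Cout,);
    output (B, Cout, F, T).
    """
    y, cols = _conv2d_same_raw(x.data, w.data)
    y += bias.data[None, :, None, None]
    out = Tensor(y, _parents=(x, w, bias))
    cout = w.data.shape[0]

    def bwd(g):
        b, _, f, t = g.shape
        g2 = g.reshape(b, cout, f * t)
        if w.requires_grad:
            dw = np.einsum("bof,bkf->ok", g2, cols, optimize=True)
            w._accum(dw.reshape(w.data.shape))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # adjoint of 'same' stride-1 cross-correlation: correlate the
            # upstream gradient with spatially flipped, channel-swapped filters
            wt = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            dx, _ = _conv2d_same_raw(g, np.ascontiguousarray(wt))
            x._accum(dx)

    out._backward = bwd
    return out


def maxpool_freq(x: Tensor, k: int) -> Tensor:
    """Max pooling with window (k, 1) and stride (k, 1): downsamples the
    frequency axis only, discarding the remainder rows, and preserves the
    temporal dimension exactly."""
    b, c, f, t = x.data.shape
    fk = f // k
    cropped = x.data[:, :, : fk * k, :].reshape(b, c, fk, k, t)
    arg = cropped.argmax(axis=3)
    y = np.take_along_axis(cropped, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    out = Tensor(y, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            buf = np.zeros((b, c, fk, k, t), dtype=x.data.dtype)
            np.put_along_axis(buf, arg[:, :, :, None, :], g[:, :, :, None, :], axis=3)
            full = np.zeros_like(x.data)
            full[:, :, : fk * k, :] = buf.reshape(b, c, fk * k, t)
            x._accum(full)

    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy between (N, C) logits and integer targets (N,)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), targets], 1e-300))
    out = Tensor(nll.mean(), _parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(n), targets] -= 1.0
            logits._accum(g * d / n)

    out._backward = bwd
    return out
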