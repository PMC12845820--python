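"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small encoder--decoder networks; this module supplies the
differentiable tensor type those networks and the loss functions are written
against.  It deliberately covers only the operations the models need (dense and
convolutional products, gated-recurrence nonlinearities, reductions, slicing)
and stores everything in float64 so finite-difference gradient checks are
meaningful at 1e-4 relative tolerance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack",
    "conv1d",
    "conv_transpose1d",
    "softmax",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a gradient and the tape edges that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: the GRU unrolls into long chains
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor._make(out, (self, other), backward)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- reductions & reshaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tensors, backward
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


# -- convolution primitives ----------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """1-D cross-correlation.  x: [B, Cin, T], w: [Cout, Cin, k] -> [B, Cout, L]."""
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, T = x.shape
    Cout, Cin_w, k = w.shape
    if Cin != Cin_w:
        raise ValueError(f"conv1d: input has {Cin} channels, kernel expects {Cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    L = (T + 2 * padding - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::stride]
    out = np.einsum("bclk,ock->bol", win, w.data, optimize=True)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out = out + b.data[None, :, None]
        parents.append(b)
    idx = np.arange(L)[:, None] * stride + np.arange(k)[None, :]

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("bol,bclk->ock", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            cols = np.einsum("bol,ock->bclk", g, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            np.add.at(dxp, (slice(None), slice(None), idx), cols)
            x._accum(dxp[:, :, padding:padding + T] if padding else dxp)

    return Tensor._make(out, parents, backward)


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """1-D transposed convolution.  x: [B, Cin, T], w: [Cin, Cout, k]."""
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, T = x.shape
    Cin_w, Cout, k = w.shape
    if Cin != Cin_w:
        raise ValueError(f"conv_transpose1d: input has {Cin} channels, kernel expects {Cin_w}")
    full_len = (T - 1) * stride + k
    idx = np.arange(T)[:, None] * stride + np.arange(k)[None, :]
    contrib = np.einsum("bct,cok->botk", x.data, w.data, optimize=True)
    full = np.zeros((B, Cout, full_len))
    np.add.at(full, (slice(None), slice(None), idx.T.ravel()),
              contrib.transpose(0, 1, 3, 2).reshape(B, Cout, -1))
    out = full[:, :, padding:full_len - padding] if padding else full
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out = out + b.data[None, :, None]
        parents.append(b)

    def backward(g):
        gf = np.pad(g, ((0, 0), (0, 0), (padding, padding))) if padding else g
        win = np.lib.stride_tricks.sliding_window_view(gf, k, axis=2)[:, :, ::stride]
        if x.requires_grad:
            x._accum(np.einsum("botk,cok->bct", win, w.data, optimize=True))
        if w.requires_grad:
            w._accum(np.einsum("botk,bct->cok", win, x.data, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))

    return Tensor._make(out, parents, backward)
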