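"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the network needs: broadcast add/mul, binary
einsum, shape ops, sigmoid / relu / softmax / log-softmax, sliding-window patch
extraction and folding, and adaptive average pooling.  Every operation's
adjoint is verified by finite differences in the test suite.

Gradients of a binary ``einsum('X,Y->Z', a, b)`` are computed as
``einsum('Z,Y->X', g, b)`` and ``einsum('Z,X->Y', g, a)``; this is exact
whenever no index is repeated within one operand spec and every index of an
operand appears in the output or the other operand — true for all specs used
here.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], tuple] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- conveniences -------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    # -- backprop -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _node(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        ga = _unbroadcast(g * b.data, a.data.shape) if a.requires_grad else None
        gb = _unbroadcast(g * a.data, b.data.shape) if b.requires_grad else None
        return ga, gb

    return _node(out, (a, b), backward)


def einsum(spec: str, a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    inputs, out_spec = spec.split("->")
    sa, sb = inputs.split(",")
    out = np.einsum(spec, a.data, b.data, optimize=True)

    def backward(g):
        ga = (
            np.einsum(f"{out_spec},{sb}->{sa}", g, b.data, optimize=True)
            if a.requires_grad
            else None
        )
        gb = (
            np.einsum(f"{out_spec},{sa}->{sb}", g, a.data, optimize=True)
            if b.requires_grad
            else None
        )
        return ga, gb

    return _node(out, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.data.shape),)

    return _node(out, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        return (np.transpose(g, inv),)

    return _node(out, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _node(out, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return (g * out * (1.0 - out),)

    return _node(out, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0)

    def backward(g):
        return (g * (a.data > 0),)

    return _node(out, (a,), backward)


def softmax(a, axis: int) -> Tensor:
    """Softmax with max subtraction along ``axis`` (value-preserving)."""
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return ((g - dot) * out,)

    return _node(out, (a,), backward)


def log_softmax(a, axis: int) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse
    sm = np.exp(out)

    def backward(g):
        return (g - sm * g.sum(axis=axis, keepdims=True),)

    return _node(out, (a,), backward)


# ---------------------------------------------------------------------------
# patch algebra (autodiff wrappers over the pure numpy kernels in `patching`)
# ---------------------------------------------------------------------------

def extract_patches_op(a, kernel: tuple[int, int], stride: int) -> Tensor:
    """Sliding-window patch extraction over the two trailing axes.

    ``(..., H, W) -> (..., kh*kw, B)``; the adjoint scatter-adds patches back.
    """
    from .patching import _extract, _scatter_add

    a = as_tensor(a)
    h, w = a.data.shape[-2:]
    out = _extract(a.data, kernel, stride)

    def backward(g):
        return (_scatter_add(g, kernel, stride, (h, w)),)

    return _node(out, (a,), backward)


def fold_patches_op(a, kernel: tuple[int, int], stride: int,
                    size: tuple[int, int]) -> Tensor:
    """Inverse of :func:`extract_patches_op`; overlaps receive the mean."""
    from .patching import _extract, _overlap_counts, _scatter_add

    a = as_tensor(a)
    counts = _overlap_counts(size, kernel, stride)
    out = _scatter_add(a.data, kernel, stride, size) / counts

    def backward(g):
        return (_extract(g / counts, kernel, stride),)

    return _node(out, (a,), backward)


# ---------------------------------------------------------------------------
# adaptive average pooling
# ---------------------------------------------------------------------------

def _pool_bins(n: int, out: int) -> list[tuple[int, int]]:
    """Bin boundaries: start = floor(i*n/out), end = ceil((i+1)*n/out)."""
    return [((i * n) // out, -((-(i + 1) * n) // out)) for i in range(out)]


def adaptive_avg_pool_axis(a, axis: int, out_size: int) -> Tensor:
    """Adaptive mean pooling of one axis down to ``out_size``."""
    a = as_tensor(a)
    n = a.data.shape[axis]
    if out_size > n:
        raise ValueError(f"pool target {out_size} exceeds input size {n}")
    if out_size == n:
        return a
    x = np.moveaxis(a.data, axis, -1)
    if n % out_size == 0:
        block = n // out_size
        out_m = x.reshape(x.shape[:-1] + (out_size, block)).mean(axis=-1)
        bins = None
    else:
        bins = _pool_bins(n, out_size)
        out_m = np.stack([x[..., s:e].mean(axis=-1) for s, e in bins], axis=-1)
    out = np.moveaxis(out_m, -1, axis)

    def backward(g):
        gm = np.moveaxis(g, axis, -1)
        gi = np.zeros_like(x)
        if bins is None:
            blk = n // out_size
            gi[...] = np.repeat(gm, blk, axis=-1) / blk
        else:
            for i, (s, e) in enumerate(bins):
                gi[..., s:e] += gm[..., i:i + 1] / (e - s)
        return (np.moveaxis(gi, -1, axis),)

    return _node(out, (a,), backward)
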