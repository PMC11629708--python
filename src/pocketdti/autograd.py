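"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small attention/convolution models on CPU, so the engine
is deliberately compact: a :class:`Tensor` wraps a float32 ``numpy`` array
and records a closure that scatters the upstream gradient to its parents.
``backward`` runs a topological sort and accumulates gradients.  Only the
operations the model needs are implemented; all of them support the
broadcasting rules of numpy (gradients are un-broadcast by summation).
"""

from __future__ import annotations

import numpy as np

try:  # fused row-softmax kernels; numpy fallback below keeps results identical
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _softmax_rows_bwd(p, g):
        for i in range(p.shape[0]):
            dot = 0.0
            for j in range(p.shape[1]):
                dot += p[i, j] * g[i, j]
            for j in range(p.shape[1]):
                g[i, j] = p[i, j] * (g[i, j] - dot)

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in supported envs
    _HAVE_NUMBA = False

__all__ = ["Tensor", "concat", "as_tensor", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        """Stop-gradient: same values, no history."""
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float32)
        # topological order over the reachable graph
        topo, seen = [], set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None  # free intermediate gradients

    def _accum(self, grad, own: bool = False):
        """Accumulate an upstream gradient.  ``own=True`` promises the caller
        hands over a freshly allocated array that no other node will touch,
        so it can be adopted without a defensive copy."""
        if self.grad is None:
            if own and grad.dtype == np.float32 and grad.flags.writeable:
                self.grad = grad
            else:
                self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            # g may be adopted (own=True) by at most one parent
            if self.requires_grad:
                gs = _unbroadcast(g, self.data.shape)
                self._accum(gs, own=True)
                if other.requires_grad:
                    go = _unbroadcast(g, other.data.shape)
                    other._accum(go, own=go is not gs and go is not g)
            elif other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape), own=True)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g, own=True)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape), own=True)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape), own=True)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape), own=True)

        return self._make(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old), own=True)

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            self._accum(np.swapaxes(g, a, b), own=True)

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = np.transpose(self.data, axes or None)
        inv = np.argsort(axes) if axes else None

        def backward(g):
            self._accum(np.transpose(g, inv), own=True)

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=np.float32)
            np.add.at(full, idx, g)
            self._accum(full, own=True)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).astype(np.float32))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accum(g * mask, own=True)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    # -- fused numerical kernels ----------------------------------------------
    def softmax(self, axis: int = -1, mask: np.ndarray | None = None):
        """Numerically stable softmax; `mask` (broadcastable, bool/0-1) marks
        valid keys — invalid positions receive exactly zero probability."""
        fused = _HAVE_NUMBA and axis in (-1, self.data.ndim - 1)
        if mask is not None:
            out_data = np.where(mask.astype(bool), self.data, np.float32(-1e30))
        else:
            out_data = self.data.copy()
        out_data -= out_data.max(axis=axis, keepdims=True)
        np.exp(out_data, out=out_data)
        out_data /= out_data.sum(axis=axis, keepdims=True)
        if mask is not None:
            out_data *= np.asarray(mask, dtype=np.float32)

        def backward(g):
            if fused and g.dtype == np.float32 and g.flags.writeable and \
                    g.flags.c_contiguous:
                cols = g.shape[-1]
                _softmax_rows_bwd(out_data.reshape(-1, cols),
                                  g.reshape(-1, cols))
                self._accum(g, own=True)
                return
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            g = g - dot  # fresh buffer
            g *= out_data
            self._accum(g, own=True)

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        x = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
        out_data = x - lse

        def backward(g):
            sm = np.exp(out_data)
            self._accum(g - sm * g.sum(axis=axis, keepdims=True), own=True)

        return self._make(out_data, (self,), backward)

    def layer_norm(self, eps: float = 1e-5):
        """Normalize over the last axis (no affine parameters)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out_data = xc * inv
        n = self.data.shape[-1]

        def backward(g):
            gm = g.mean(axis=-1, keepdims=True)
            gxm = (g * out_data).mean(axis=-1, keepdims=True)
            self._accum(inv * (g - gm - out_data * gxm), own=True)

        return self._make(out_data, (self,), backward)

    def embedding(self, ids: np.ndarray):
        """Row lookup `self[ids]` where self is a (V, d) table."""
        ids = np.asarray(ids)
        out_data = self.data[ids]
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=np.float32)
            np.add.at(full, ids.reshape(-1), g.reshape(-1, shape[-1]))
            self._accum(full, own=True)

        return self._make(out_data, (self,), backward)

    def unfold(self, size: int, pad: int):
        """Sliding windows along axis -2 of a (..., L, C) tensor with symmetric
        zero padding so the output length equals L: (..., L, size*C)."""
        k, c = size, self.data.shape[-1]
        length = self.data.shape[-2]
        padded = np.pad(
            self.data,
            [(0, 0)] * (self.data.ndim - 2) + [(pad, size - 1 - pad), (0, 0)],
        )
        win = np.lib.stride_tricks.sliding_window_view(padded, (k, c), axis=(-2, -1))
        out_data = np.ascontiguousarray(win.reshape(self.data.shape[:-2] + (length, k * c)))

        def backward(g):
            gp = np.zeros_like(padded)
            g = g.reshape(g.shape[:-1] + (k, c))
            for j in range(k):
                gp[..., j : j + length, :] += g[..., :, j, :]
            sl = [slice(None)] * (self.data.ndim - 2) + [
                slice(pad, pad + length),
                slice(None),
            ]
            self._accum(np.ascontiguousarray(gp[tuple(sl)]), own=True)

        return self._make(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out = Tensor(out_data)
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
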