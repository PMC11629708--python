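"""Neural-network building blocks on top of :mod:`pocketdti.autograd`.

Layers follow the conventions of mainstream deep-learning libraries:
``Module`` collects parameters recursively, ``Linear`` stores a (in, out)
weight, attention uses scaled dot products with additive key masking.
Initialisation is Glorot-uniform from an explicit ``numpy.random.Generator``
so every model build is reproducible from a single integer seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Embedding",
    "Conv1dSame",
    "BatchNorm1d",
    "FeedForward",
    "Adapter",
    "MLP",
    "MultiHeadAttention",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        seen = set()
        stack = [self]
        while stack:
            mod = stack.pop()
            for v in vars(mod).values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    out.append(v)
                elif isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Module):
                            stack.append(item)
        return out

    def modules(self):
        out = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.parameters())

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            p.data[...] = state[f"p{i}"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out)).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((d_in, d_out), dtype=np.float32)
        else:
            w = glorot(rng, d_in, d_out)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        # flatten leading axes into one big GEMM (much faster than numpy's
        # per-slice batched matmul, forward and backward)
        lead = x.shape[:-1]
        flat = x.reshape((-1, x.shape[-1])) if len(lead) > 1 else x
        y = flat @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y.reshape(lead + (y.shape[-1],)) if len(lead) > 1 else y


class Embedding(Module):
    """Trainable lookup table; row 0 (pad) is held at zero by construction."""

    def __init__(self, vocab: int, dim: int, rng: np.random.Generator,
                 zero_pad_row: bool = True):
        super().__init__()
        w = (rng.standard_normal((vocab, dim)) * 0.1).astype(np.float32)
        if zero_pad_row:
            w[0] = 0.0
        self.weight = Parameter(w)

    def forward(self, ids: np.ndarray) -> Tensor:
        return self.weight.embedding(np.asarray(ids))


class Conv1dSame(Module):
    """1-D convolution over (..., L, C_in), stride 1, zero same-padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        self.weight = Parameter(glorot(rng, kernel * c_in, c_out))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        cols = x.unfold(self.kernel, self.pad)
        return cols @ self.weight + self.bias


class BatchNorm1d(Module):
    """Parameter-less batch normalization over all leading axes per channel.

    ``training`` mode uses batch statistics and updates running estimates;
    ``eval`` mode uses the running estimates; setting ``frozen`` pins the
    layer to its stored statistics in every mode (deterministic unit tests).
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.frozen = False
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training and not self.frozen:
            axes = tuple(range(x.ndim - 1))
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            mean_t = x.mean(axis=axes, keepdims=True)
            centered = x - mean_t
            var_t = (centered * centered).mean(axis=axes, keepdims=True)
            return centered * (var_t + self.eps).pow(-0.5)
        # fixed statistics: an affine map, fully deterministic
        scale = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * scale


class FeedForward(Module):
    """Two-layer position-wise feed-forward block mapping width d -> h."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 hidden: int | None = None):
        super().__init__()
        hidden = hidden or d_out
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, d_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class Adapter(Module):
    """Bottleneck adapter with residual connection (parameter-efficient head).

    The up-projection is zero-initialised so the adapter is the identity at
    initialisation, the standard safe insertion into a frozen embedder.
    """

    def __init__(self, dim: int, bottleneck: int, rng: np.random.Generator):
        super().__init__()
        self.down = Linear(dim, bottleneck, rng)
        self.up = Linear(bottleneck, dim, rng, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.up(self.down(x).relu())


class MLP(Module):
    """Stack of ReLU hidden layers with a linear output layer."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 zero_init_last: bool = False):
        super().__init__()
        self.layers = [
            Linear(dims[i], dims[i + 1], rng,
                   zero_init=zero_init_last and i == len(dims) - 2)
            for i in range(len(dims) - 1)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         key_mask: np.ndarray | None = None):
    """Multi-head scaled dot-product attention core.

    q: (..., H, Tq, dk), k/v: (..., H, Tk, dk); key_mask broadcastable to
    (..., 1, 1, Tk).  Returns (output, attention weights).
    """
    dk = q.shape[-1]
    scores = (q * (1.0 / math.sqrt(dk))) @ k.swapaxes(-1, -2)
    attn = scores.softmax(axis=-1, mask=key_mask)
    return attn @ v, attn


class MultiHeadAttention(Module):
    """Standard multi-head attention with separate W_q/W_k/W_v and an output
    projection; returns both the result and the per-head attention weights."""

    def __init__(self, h: int, n_heads: int, rng: np.random.Generator,
                 zero_init_out: bool = False):
        super().__init__()
        if h % n_heads:
            raise ValueError(f"model width {h} not divisible by {n_heads} heads")
        self.h = h
        self.n_heads = n_heads
        self.dk = h // n_heads
        self.wq = Linear(h, h, rng, bias=False)
        self.wk = Linear(h, h, rng, bias=False)
        self.wv = Linear(h, h, rng, bias=False)
        self.wo = Linear(h, h, rng, zero_init=zero_init_out)

    def _split(self, x: Tensor) -> Tensor:
        # (..., T, h) -> (..., H, T, dk)
        t = x.shape[-2]
        return x.reshape(x.shape[:-2] + (t, self.n_heads, self.dk)).swapaxes(-2, -3)

    def _merge(self, x: Tensor) -> Tensor:
        t = x.shape[-2]
        return x.swapaxes(-2, -3).reshape(x.shape[:-3] + (t, self.h))

    def forward(self, query: Tensor, key: Tensor, value: Tensor,
                key_mask: np.ndarray | None = None):
        q = self._split(self.wq(query))
        k = self._split(self.wk(key))
        v = self._split(self.wv(value))
        if key_mask is not None:
            key_mask = np.asarray(key_mask)[..., None, None, :]
        out, attn = scaled_dot_attention(q, k, v, key_mask)
        return self.wo(self._merge(out)), attn


class Adam(Module):
    """Adaptive-moment optimizer (decoupled from any global state)."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__()
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
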