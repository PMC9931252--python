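"""Minimal reverse-mode automatic differentiation over numpy arrays.

The two trainable models in this package (the pointer-network segment
splitter and the unit-classification summarizer) are small enough to train on
one CPU in double precision.  This module provides the tensor/graph machinery
they share: broadcast-aware elementwise ops, matmul, gather, softmax,
layer norm, fused stable losses, and an Adam optimizer.

Everything is float64 and seeded explicitly; a forward pass is a pure
function of weights and input, which the pipeline's determinism contract
relies on.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------

    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _const(-1.0)))

    def __neg__(self):
        return mul(self, _const(-1.0))

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _const(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64))


def _accum(t: Tensor, g: np.ndarray) -> None:
    g = _unbroadcast(g, t.data.shape)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitive ops


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out._backward = lambda g: (_accum(a, g), _accum(b, g))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out._backward = lambda g: (_accum(a, g * b.data), _accum(b, g * a.data))
    return out


def power(a: Tensor, p: float) -> Tensor:
    out = Tensor(a.data**p, (a,))
    out._backward = lambda g: _accum(a, g * p * a.data ** (p - 1.0))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def _bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = _bw
    return out


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)
    out = Tensor(e, (a,))
    out._backward = lambda g: _accum(a, g * e)
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), (a,))
    out._backward = lambda g: _accum(a, g / a.data)
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))
    out._backward = lambda g: _accum(a, g * (1.0 - t * t))
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, (a,))
    out._backward = lambda g: _accum(a, g * s * (1.0 - s))
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out._backward = lambda g: _accum(a, g * mask)
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def _bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g, a.data.shape))

    out._backward = _bw
    return out


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), _const(1.0 / n))


def transpose(a: Tensor) -> Tensor:
    out = Tensor(a.data.T, (a,))
    out._backward = lambda g: _accum(a, g.T)
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))
    out._backward = lambda g: _accum(a, g.reshape(a.data.shape))
    return out


def getitem(a: Tensor, idx) -> Tensor:
    out = Tensor(a.data[idx], (a,))

    def _bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        if a.grad is None:
            a.grad = full
        else:
            a.grad += full

    out._backward = _bw
    return out


def take_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of an embedding table; duplicate rows accumulate grads."""
    idx = np.asarray(indices, dtype=np.intp)
    out = Tensor(table.data[idx], (table,))

    def _bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        if table.grad is None:
            table.grad = full
        else:
            table.grad += full

    out._backward = _bw
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw(g):
        offset = 0
        for t, size in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offset, offset + size)
            _accum(t, g[tuple(sl)])
            offset += size

    out._backward = _bw
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D matrix (rows)."""
    out = Tensor(np.stack([t.data for t in tensors]), tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            _accum(t, g[i])

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# composite ops


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = _const(np.max(a.data, axis=axis, keepdims=True))  # detached, shift-invariant
    e = exp(a - shift)
    return e / tsum(e, axis=axis, keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis of a (T, d) tensor."""
    mu = tmean(x, axis=-1, keepdims=True)
    xc = x - mu
    var = tmean(mul(xc, xc), axis=-1, keepdims=True)
    inv = power(add(var, _const(eps)), -0.5)
    return mul(mul(xc, inv), gamma) + beta


def cross_entropy_logits(scores: Tensor, target: int) -> Tensor:
    """Stable -log softmax(scores)[target] for a 1-D score vector."""
    m = float(np.max(scores.data))
    z = scores.data - m
    lse = m + float(np.log(np.sum(np.exp(z))))
    out = Tensor(lse - scores.data[target], (scores,))
    probs = np.exp(z) / np.sum(np.exp(z))

    def _bw(g):
        grad = probs.copy()
        grad[target] -= 1.0
        _accum(scores, g * grad)

    out._backward = _bw
    return out


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy between sigmoid(logits) and 0/1 labels."""
    y = np.asarray(labels, dtype=np.float64)
    z = logits.data
    # log(1+exp(-|z|)) + max(z,0) - z*y  is the stable elementwise BCE
    elem = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y
    out = Tensor(np.array(elem.mean()), (logits,))
    s = 1.0 / (1.0 + np.exp(-z))

    def _bw(g):
        _accum(logits, g * (s - y) / y.size)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# parameters and optimization


def glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encodings, shape (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


class Adam:
    """Adam over a dict of named parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def save_params(path, params: dict[str, Tensor], meta: dict) -> None:
    """Single-file checkpoint: weights plus JSON-serializable metadata."""
    import json

    arrays = {k: p.data for k, p in params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_params(path) -> tuple[dict[str, Tensor], dict]:
    import json

    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        params = {
            k: Tensor(archive[k]) for k in archive.files if k != "__meta__"
        }
    return params, meta
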