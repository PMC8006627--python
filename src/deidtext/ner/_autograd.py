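"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for linear-chain CRF training on top of recurrent and
convolutional encoders: broadcast-aware add/mul, matmul, pointwise
nonlinearities, concatenation/slicing, gather (embedding lookup) and a
numerically stable log-sum-exp.  Everything is float64 and single-threaded;
given a fixed seed the whole training loop is bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the tape machinery to backpropagate through it."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    # defer to Tensor's reflected operators instead of building object arrays
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal -----------------------------------------------------

    def backward(self):
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g, self.shape))
            _accum(other, _unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g * other.data, self.shape))
            _accum(other, _unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            _accum(self, g @ other.data.T)
            _accum(other, self.data.T @ g)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            _accum(self, full)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: _accum(self, g.reshape(self.shape))
        return out

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), (self,))

        def bw(g):
            if axis is None:
                _accum(self, np.broadcast_to(g, self.shape).copy())
            else:
                _accum(self, np.broadcast_to(
                    np.expand_dims(g, axis), self.shape).copy())

        out._backward = bw
        return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


# -- pointwise nonlinearities ------------------------------------------------

def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: _accum(x, g * (1.0 - y * y))
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(y, (x,))
    out._backward = lambda g: _accum(x, g * y * (1.0 - y))
    return out


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    out = Tensor(y, (x,))
    out._backward = lambda g: _accum(x, g * (x.data > 0))
    return out


# -- structural ops ----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 tuple(tensors))

    def bw(g):
        for t, piece in zip(tensors, np.moveaxis(g, axis, 0)):
            _accum(t, piece)

    out._backward = bw
    return out


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather (embedding lookup) with scatter-add backward."""
    idx = np.asarray(idx)
    out = Tensor(x.data[idx], (x,))

    def bw(g):
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        _accum(x, full)

    out._backward = bw
    return out


def logsumexp(x: Tensor, axis: int) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    y = m + np.log(np.sum(np.exp(x.data - m), axis=axis, keepdims=True))
    out = Tensor(np.squeeze(y, axis=axis), (x,))
    soft = np.exp(x.data - y)

    def bw(g):
        _accum(x, np.expand_dims(g, axis) * soft)

    out._backward = bw
    return out


def amax(x: Tensor, axis: int) -> Tensor:
    """Max along one axis; gradient flows to the first maximal entry."""
    idx = np.argmax(x.data, axis=axis)
    out = Tensor(np.max(x.data, axis=axis), (x,))

    def bw(g):
        full = np.zeros_like(x.data)
        grid = np.indices(idx.shape)
        index = list(grid)
        index.insert(axis if axis >= 0 else x.data.ndim + axis, idx)
        full[tuple(index)] = g
        _accum(x, full)

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when ``p == 0``."""
    if p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
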