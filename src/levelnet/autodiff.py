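"""A small reverse-mode automatic-differentiation engine over numpy arrays.

This is the numerical core of the package: dense, convolutional and
tensor-interaction networks are all expressed as compositions of the tensor
operations below, and gradients for Adam training come from one backward
sweep of the recorded computation graph (standard reverse-mode AD, the same
scheme behind backpropagation in the large frameworks, reduced to the ops
this package needs).

Conventions:
* all operands are float64 numpy arrays; Python scalars are promoted;
* broadcasting follows numpy; backward passes sum gradients back over
  broadcast axes;
* ``Tensor.backward()`` seeds the output gradient with ones and accumulates
  ``.grad`` on every tensor with ``requires_grad``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- graph mechanics -----------------------------------------------------
    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __pow__(self, p: float):
        out = Tensor(self.data ** p)
        out._parents = (self,)

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad or self._parents:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._parents:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bw
        return out

    # -- nonlinearities ------------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y)
        out._parents = (self,)

        def bw(g):
            self._accum(g * (1.0 - y * y))
        out._backward = bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask)
        out._parents = (self,)

        def bw(g):
            self._accum(g * mask)
        out._backward = bw
        return out

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._parents = (self,)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        out._parents = (self,)
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))
        out._backward = bw
        return out

    def transpose(self, axes: Sequence[int]):
        out = Tensor(self.data.transpose(axes))
        out._parents = (self,)
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))
        out._backward = bw
        return out

    def max(self, axis: int):
        """Max over one axis; gradient flows to the (first) argmax."""
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)
        out = Tensor(np.take_along_axis(self.data, idx, axis=axis).squeeze(axis))
        out._parents = (self,)

        def bw(g):
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, idx, np.expand_dims(g, axis), axis=axis)
            self._accum(gx)
        out._backward = bw
        return out

    def take_rows(self, index: np.ndarray):
        """Gather rows: out[...] = self[index[...], :] (embedding lookup)."""
        index = np.asarray(index, dtype=np.int64)
        out = Tensor(self.data[index])
        out._parents = (self,)

        def bw(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, index, g)
            self._accum(gx)
        out._backward = bw
        return out

    def col_gather(self, index: np.ndarray):
        """out[b, ...] = self[b, index[...]] for a 2-D self (B, M)."""
        index = np.asarray(index, dtype=np.int64)
        out = Tensor(self.data[:, index])
        out._parents = (self,)
        b = self.data.shape[0]

        def bw(g):
            gx = np.zeros_like(self.data)
            batch = np.arange(b).reshape((b,) + (1,) * index.ndim)
            np.add.at(gx, (batch, index[None]), g)
            self._accum(gx)
        out._backward = bw
        return out


def parameter(array: np.ndarray) -> Tensor:
    return Tensor(array, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Adam:
    """Adam optimizer (β1=0.9, β2=0.999, ε=1e-8) over a parameter list."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
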