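"""Minimal reverse-mode automatic differentiation over dense numpy arrays.

The graph-attention encoder and the task heads are small full-batch models
(a few hundred genes, a handful of weight matrices), so a compact tape-based
engine over float64 numpy arrays is sufficient and keeps the whole training
loop single-threaded and bit-reproducible.  Only the operations the models
need are implemented: affine maps, elementwise activations, masked row-wise
softmax, gathering, concatenation and the two loss reductions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "masked_softmax_rows", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer `ndarray <op> Tensor` to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: (g.T,)
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g, self.data.shape),
            _unbroadcast(g, other.data.shape),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g * other.data, self.data.shape),
            _unbroadcast(g * self.data, other.data.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by python scalars")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, parents=(self, other))

        def back(g):
            if a.ndim == 2 and b.ndim == 2:
                return g @ b.T, a.T @ g
            if a.ndim == 2 and b.ndim == 1:   # (n,k)@(k,) -> (n,)
                return np.outer(g, b), a.T @ g
            if a.ndim == 1 and b.ndim == 2:   # (k,)@(k,m) -> (m,)
                return g @ b.T, np.outer(a, g)
            return g * b, g * a               # (k,)@(k,) -> scalar

        out._backward = back
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = back
        return out

    # -- elementwise ------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through unclipped entries only."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        out._backward = lambda g: (g * inside,)
        return out

    def relu(self):
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, 0.0), parents=(self,))
        out._backward = lambda g: (g * pos,)
        return out

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, slope * self.data), parents=(self,))
        out._backward = lambda g: (g * np.where(pos, 1.0, slope),)
        return out

    def elu(self):
        pos = self.data > 0
        ex = np.exp(np.minimum(self.data, 0.0))
        out = Tensor(np.where(pos, self.data, ex - 1.0), parents=(self,))
        out._backward = lambda g: (g * np.where(pos, 1.0, ex),)
        return out

    def softplus(self):
        """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
        val = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        out = Tensor(val, parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda g: (g * sig,)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: (g * val * (1.0 - val),)
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def masked_softmax_rows(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to `mask` (boolean); masked-out cells are 0.

    Every row must contain at least one True cell.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=1).all():
        raise ValueError("masked softmax: some row has an empty neighborhood")
    neg = np.where(mask, scores.data, -np.inf)
    m = neg.max(axis=1, keepdims=True)
    p = np.exp(neg - m)
    p = p / p.sum(axis=1, keepdims=True)
    out = Tensor(p, parents=(scores,))

    def back(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        return (p * (g - dot),)

    out._backward = back
    return out


class Adam:
    """Adam optimizer over a list of leaf Tensors (full-batch use)."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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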