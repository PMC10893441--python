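"""Minimal reverse-mode automatic differentiation over numpy arrays.

The adaptation networks in this package are small stacks of dense layers
(hundreds of weights, batch sizes in the tens), so a compact tape-based
engine is sufficient: every :class:`Tensor` records the operation that
produced it and a closure that routes the upstream gradient to its parents.
Broadcasting follows numpy rules; gradients of broadcast operands are
summed back to the operand's shape.

Gradients are accumulated (``+=``) into ``Tensor.grad``; call
:meth:`Tensor.backward` on a scalar result. Higher-order derivatives are
not supported — code that needs an input gradient inside a training loss
(e.g. the one-step perturbation surrogate) evaluates it in a detached side
graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "grad_reverse",
    "Adam",
    "RMSProp",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # ---- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        # clear stale gradients on intermediate nodes so that a second
        # backward pass over a shared subgraph does not re-propagate the
        # first pass's contributions (leaf/parameter grads accumulate)
        for t in topo:
            if t._backward is not None:
                t.grad = None
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))

        def bwd(g):
            self._accum(g)
            other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 1:
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            elif a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
            else:
                self._accum(g @ b.T)
                other._accum(a.T @ g)

        out._backward = bwd
        return out

    @property
    def T(self) -> "Tensor":
        out = _make(self.data.T, (self,))
        out._backward = lambda g: self._accum(g.T)
        return out

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = _make(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    # ---- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ---- elementwise nonlinearities ---------------------------------------

    def exp(self) -> "Tensor":
        out = _make(np.exp(self.data), (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = _make(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    def relu(self) -> "Tensor":
        out = _make(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def softplus(self) -> "Tensor":
        # numerically stable log(1+exp(x))
        s = np.logaddexp(0.0, self.data)
        out = _make(s, (self,))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda g: self._accum(g * sig)
        return out

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient passes only where unclipped."""
        out = _make(np.clip(self.data, lo, hi), (self,))
        mask = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _make(data: np.ndarray, prev: tuple) -> Tensor:
    out = Tensor(data)
    out._prev = tuple(p for p in prev if isinstance(p, Tensor))
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out


def grad_reverse(x: Tensor, coeff: float = 1.0) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by ``-coeff``.

    The standard single-optimizer trick for min–max objectives: parameters
    upstream of this node receive the reversed gradient and therefore
    ascend the objective the downstream parameters descend.
    """
    out = _make(x.data.copy(), (x,))
    out._backward = lambda g: x._accum(-coeff * g)
    return out


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class _Optimizer:
    def __init__(self, params):
        self.params = [p for p in params if p.requires_grad]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class Adam(_Optimizer):
    """Adam with L2 weight decay folded into the gradient (torch convention)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        super().__init__(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp(_Optimizer):
    """RMSProp with heavy-ball momentum (torch convention)."""

    def __init__(self, params, lr=1e-3, alpha=0.99, eps=1e-8, momentum=0.9):
        super().__init__(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.momentum = momentum
        self.sq = [np.zeros_like(p.data) for p in self.params]
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.sq[i] = self.alpha * self.sq[i] + (1 - self.alpha) * g * g
            upd = g / (np.sqrt(self.sq[i]) + self.eps)
            if self.momentum:
                self.buf[i] = self.momentum * self.buf[i] + upd
                upd = self.buf[i]
            p.data -= self.lr * upd
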