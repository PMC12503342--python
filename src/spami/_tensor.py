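"""Minimal reverse-mode automatic differentiation over numpy arrays.

The integration model is small (two-layer graph-convolutional encoders and
decoders, a bilinear discriminator per modality and a shared attention
scorer), full-batch, and CPU-bound, so a compact tape-based engine is all
that is required.  Only the operations the model uses are implemented:
dense and sparse-constant matrix products, broadcasting arithmetic, the
activations (ReLU, tanh, sigmoid, softplus), reductions, concatenation,
slicing and a row-wise softmax.  Gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import scipy.sparse as sp


class Tensor:
    """A numpy array with an optional gradient tape entry.

    Parameters
    ----------
    data : array-like
        Wrapped value; converted to a float64 ndarray.
    requires_grad : bool
        Leaf tensors with ``requires_grad=True`` accumulate gradients in
        ``.grad`` when :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        # float32 is preserved (training fast path); everything else is float64
        if data.dtype != np.float32:
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (a scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on a non-scalar requires an explicit gradient")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            order.append(node)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar -------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    @property
    def T(self) -> "Tensor":
        return transpose(self)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast axes so it matches ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _node(data: np.ndarray, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(p for p in parents)
    tracked = tuple(p for p in parents if p.requires_grad or p._parents)
    out = Tensor(data)
    if tracked:
        out._parents = tracked
        out._backward = backward
    return out


# -- arithmetic ---------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

    return _node(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.shape)),
            (b, _unbroadcast(g * a.data, b.shape)),
        )

    return _node(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data / b.data

    def backward(g):
        return (
            (a, _unbroadcast(g / b.data, a.shape)),
            (b, _unbroadcast(-g * a.data / b.data**2, b.shape)),
        )

    return _node(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data @ b.data

    def backward(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return _node(data, (a, b), backward)


def spmm(A: sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a dense tensor."""
    x = _wrap(x)
    A = A.tocsr()
    data = A @ x.data

    def backward(g):
        return ((x, A.T @ g),)

    return _node(data, (x,), backward)


# -- activations --------------------------------------------------------------


def relu(x) -> Tensor:
    x = _wrap(x)
    data = np.maximum(x.data, 0.0)

    def backward(g):
        return ((x, g * (x.data > 0)),)

    return _node(data, (x,), backward)


def tanh(x) -> Tensor:
    x = _wrap(x)
    data = np.tanh(x.data)

    def backward(g):
        return ((x, g * (1.0 - data**2)),)

    return _node(data, (x,), backward)


def sigmoid(x) -> Tensor:
    x = _wrap(x)
    data = _sigmoid_stable(x.data)

    def backward(g):
        return ((x, g * data * (1.0 - data)),)

    return _node(data, (x,), backward)


def _sigmoid_stable(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(x) -> Tensor:
    """log(1 + exp(x)), overflow-safe; building block of log-sigmoid."""
    x = _wrap(x)
    data = np.logaddexp(0.0, x.data)

    def backward(g):
        return ((x, g * _sigmoid_stable(x.data)),)

    return _node(data, (x,), backward)


def log_sigmoid(x) -> Tensor:
    """log σ(x) = −softplus(−x), numerically stable at both tails."""
    return mul(softplus(mul(_wrap(x), -1.0)), -1.0)


def sqrt(x) -> Tensor:
    x = _wrap(x)
    data = np.sqrt(x.data)

    def backward(g):
        return ((x, g * 0.5 / data),)

    return _node(data, (x,), backward)


# -- reductions & shape ops ---------------------------------------------------


def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((x, np.broadcast_to(g, x.shape).copy()),)

    return _node(data, (x,), backward)


def tmean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return _node(data, tensors, backward)


def take(x, idx) -> Tensor:
    x = _wrap(x)
    data = x.data[idx]

    def backward(g):
        out = np.zeros_like(x.data)
        np.add.at(out, idx, g)
        return ((x, out),)

    return _node(data, (x,), backward)


def transpose(x) -> Tensor:
    x = _wrap(x)
    data = x.data.T

    def backward(g):
        return ((x, g.T),)

    return _node(data, (x,), backward)


def softmax(x, axis: int = -1) -> Tensor:
    x = _wrap(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    data = ez / ez.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        return ((x, data * (g - dot)),)

    return _node(data, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero entries w.p. ``p`` and rescale by 1/(1−p)."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"dropout probability must be in [0, 1), got {p}")
    if p == 0.0:
        return _wrap(x)
    x = _wrap(x)
    mask = ((rng.random(x.shape) >= p) / (1.0 - p)).astype(x.data.dtype)
    return mul(x, mask)


class Adam:
    """Adam optimizer with the standard default moments (β1=0.9, β2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
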