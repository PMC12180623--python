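"""Minimal reverse-mode automatic differentiation over numpy arrays.

The simulator needs gradients of a scalar loss with respect to weights and
time constants through an unrolled recurrent computation, including a custom
surrogate derivative at the spike threshold.  This module provides exactly
that: a :class:`Tensor` wrapping an ``ndarray``, a small set of differentiable
operations (enough for leaky integration, bounded dendritic coupling,
softmax classification losses and quadratic regularisers), and a
tape/topological-sort backward pass.

Only leaf tensors (``requires_grad=True`` and no parents) accumulate ``.grad``;
intermediate gradients live in a scratch dict during ``backward`` and are
freed afterwards.  Gradient correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "as_tensor",
    "custom_op",
    "tanh",
    "exp",
    "log",
    "sqrt",
    "absolute",
    "tensor_sum",
    "tensor_mean",
    "matmul",
    "cross_entropy",
    "log_softmax",
    "l2_normalize",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp", "name")

    # make numpy defer to the reflected operators (ndarray * Tensor etc.)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._vjp = None
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False, name=self.name)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        flag = ", requires_grad=True" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    # --------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        # postorder DFS -> topo order (inputs first), then sweep in reverse
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is not None:
                parent_grads = node._vjp(g)
                for parent, pg in zip(node._parents, parent_grads):
                    if pg is None:
                        continue
                    if not (parent.requires_grad or parent._parents):
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return custom_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self) -> "Tensor":
        return custom_op(self.data.T, (self,), lambda g: (g.T,))

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def custom_op(data: np.ndarray, parents: tuple, vjp) -> Tensor:
    """Create the result tensor of an operation.

    ``vjp(out_grad)`` must return one (possibly ``None``) gradient per parent,
    already reduced to each parent's shape.
    """
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._vjp = vjp
    return out


# --------------------------------------------------------------- elementwise
def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return custom_op(
        a.data + b.data, (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return custom_op(
        a.data * b.data, (a, b),
        lambda g: (_unbroadcast(g * b.data, a.data.shape),
                   _unbroadcast(g * a.data, b.data.shape)),
    )


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def vjp(g):
        return (_unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return custom_op(out, (a, b), vjp)


def power(a, exponent: float):
    a = as_tensor(a)
    exponent = float(exponent)
    out = a.data ** exponent
    return custom_op(out, (a,),
                     lambda g: (g * exponent * a.data ** (exponent - 1.0),))


def _dispatch(x, tensor_fn, array_fn):
    if isinstance(x, Tensor):
        return tensor_fn(x)
    return array_fn(np.asarray(x))


def tanh(x):
    def t(a: Tensor):
        out = np.tanh(a.data)
        return custom_op(out, (a,), lambda g: (g * (1.0 - out ** 2),))

    return _dispatch(x, t, np.tanh)


def exp(x):
    def t(a: Tensor):
        out = np.exp(a.data)
        return custom_op(out, (a,), lambda g: (g * out,))

    return _dispatch(x, t, np.exp)


def log(x):
    def t(a: Tensor):
        return custom_op(np.log(a.data), (a,), lambda g: (g / a.data,))

    return _dispatch(x, t, np.log)


def sqrt(x):
    def t(a: Tensor):
        out = np.sqrt(a.data)
        return custom_op(out, (a,), lambda g: (g * 0.5 / out,))

    return _dispatch(x, t, np.sqrt)


def absolute(x):
    """|x| with the subgradient sign(x) (0 at the kink)."""

    def t(a: Tensor):
        return custom_op(np.abs(a.data), (a,), lambda g: (g * np.sign(a.data),))

    return _dispatch(x, t, np.abs)


# ---------------------------------------------------------------- reductions
def tensor_sum(x, axis=None, keepdims=False):
    def t(a: Tensor):
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return custom_op(out, (a,), vjp)

    return _dispatch(x, t, lambda arr: arr.sum(axis=axis, keepdims=keepdims))


def tensor_mean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        n = x.data.size if axis is None else x.data.shape[axis]
        return tensor_sum(x, axis=axis, keepdims=keepdims) * (1.0 / n)
    return np.asarray(x).mean(axis=axis, keepdims=keepdims)


# -------------------------------------------------------------------- linalg
def matmul(a, b):
    """2-D matrix product with gradients (``(m,k) @ (k,n)``)."""
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def vjp(g):
        return (g @ b.data.T, a.data.T @ g)

    return custom_op(out, (a, b), vjp)


def l2_normalize(x, axis=-1, eps: float = 1e-12):
    """x / ||x||_2 along ``axis``; the all-zero vector maps to zero."""
    if isinstance(x, Tensor):
        sq = tensor_sum(x * x, axis=axis, keepdims=True)
        return x / sqrt(sq + eps)
    x = np.asarray(x, dtype=np.float64)
    norm = np.sqrt((x * x).sum(axis=axis, keepdims=True) + eps)
    return x / norm


# --------------------------------------------------------------------- loss
def log_softmax(x, axis=-1):
    def t(a: Tensor):
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        logits = shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        softmax = np.exp(logits)

        def vjp(g):
            return (g - softmax * g.sum(axis=axis, keepdims=True),)

        return custom_op(logits, (a,), vjp)

    def arr(a: np.ndarray):
        shifted = a - a.max(axis=axis, keepdims=True)
        return shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))

    return _dispatch(x, t, arr)


def cross_entropy(logits, labels) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under
    ``log_softmax(logits)``; fused op for a stable backward pass."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    data = logits.data
    if data.ndim == 1:
        data = data[None, :]
        labels = np.atleast_1d(labels)
    if labels.shape[0] != data.shape[0]:
        raise ValueError("label batch does not match logits batch")
    if labels.min() < 0 or labels.max() >= data.shape[1]:
        raise ValueError("label outside [0, n_classes)")
    shifted = data - data.max(axis=1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    batch = data.shape[0]
    loss = -logp[np.arange(batch), labels].mean()

    def vjp(g):
        softmax = np.exp(logp)
        softmax[np.arange(batch), labels] -= 1.0
        grad = g * softmax / batch
        return (grad.reshape(logits.data.shape),)

    return custom_op(loss, (logits,), vjp)
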