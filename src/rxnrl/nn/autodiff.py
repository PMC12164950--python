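"""A compact vectorized reverse-mode automatic-differentiation engine on numpy.

Every tensor op builds a node in a dynamic computation graph; ``Tensor.backward``
runs reverse-mode accumulation over a topological ordering.  Gradients for all
ops are exercised against central finite differences in the test suite.

Inference can skip graph construction entirely via the :func:`no_grad` context,
which makes decoding loops cheap.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True

#: Array dtype of the engine.  float32 is the training default; tests that
#: compare against finite differences switch to float64 for headroom.
DTYPE = np.float32


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=DTYPE)


class Tensor:
    """An n-d array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = data if isinstance(data, np.ndarray) else _as_array(data)
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        t = Tensor(np.asarray(data, dtype=DTYPE))
        t.requires_grad = True  # parameters stay trainable even under no_grad
        return t

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None


def _binary(a: Tensor, b, fwd, bwd_a, bwd_b) -> Tensor:
    b = b if isinstance(b, Tensor) else Tensor(b)
    out = Tensor(fwd(a.data, b.data))
    if _GRAD_ENABLED and (a.requires_grad or b.requires_grad):
        out.requires_grad = True
        out._parents = tuple(p for p in (a, b) if p.requires_grad)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(bwd_a(g, a.data, b.data), a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(bwd_b(g, a.data, b.data), b.data.shape))

        out._backward = backward
    return out


def _unary(a: Tensor, fwd_data, bwd) -> Tensor:
    out = Tensor(fwd_data)
    if _GRAD_ENABLED and a.requires_grad:
        out.requires_grad = True
        out._parents = (a,)

        def backward(g):
            a._accumulate(bwd(g))

        out._backward = backward
    return out


# rebind arithmetic as module functions on the class ------------------------------

def _add(self, other):
    return _binary(self, other, lambda x, y: x + y, lambda g, x, y: g, lambda g, x, y: g)


def _sub(self, other):
    return _binary(self, other, lambda x, y: x - y, lambda g, x, y: g, lambda g, x, y: -g)


def _rsub(self, other):
    return _binary(self, other, lambda x, y: y - x, lambda g, x, y: -g, lambda g, x, y: g)


def _mul(self, other):
    return _binary(self, other, lambda x, y: x * y, lambda g, x, y: g * y, lambda g, x, y: g * x)


def _truediv(self, other):
    return _binary(
        self, other,
        lambda x, y: x / y,
        lambda g, x, y: g / y,
        lambda g, x, y: -g * x / (y * y),
    )


def _neg(self):
    return _unary(self, -self.data, lambda g: -g)


def _matmul(self, other):
    other = other if isinstance(other, Tensor) else Tensor(other)

    def bwd_a(g, x, y):
        return np.matmul(g, np.swapaxes(y, -1, -2))

    def bwd_b(g, x, y):
        return np.matmul(np.swapaxes(x, -1, -2), g)

    return _binary(self, other, np.matmul, bwd_a, bwd_b)


def _pow(self, p: float):
    return _unary(self, self.data**p, lambda g: g * p * self.data ** (p - 1))


Tensor.__add__ = _add
Tensor.__radd__ = _add
Tensor.__sub__ = _sub
Tensor.__rsub__ = _rsub
Tensor.__mul__ = _mul
Tensor.__rmul__ = _mul
Tensor.__truediv__ = _truediv
Tensor.__neg__ = _neg
Tensor.__matmul__ = _matmul
Tensor.__pow__ = _pow


# shape ops ----------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return _unary(a, a.data.reshape(shape), lambda g: g.reshape(old))


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    return _unary(a, a.data.transpose(axes), lambda g: g.transpose(inv))


def getitem(a: Tensor, idx) -> Tensor:
    def bwd(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return out

    return _unary(a, a.data[idx], bwd)


Tensor.reshape = reshape
Tensor.transpose = transpose
Tensor.__getitem__ = getitem


# reductions ---------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def bwd(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.data.shape).copy()

    return _unary(a, a.data.sum(axis=axis, keepdims=keepdims), bwd)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


Tensor.sum = tsum
Tensor.mean = tmean


# nonlinearities -----------------------------------------------------------------

def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    return _unary(a, out_data, lambda g: g * out_data)


def log(a: Tensor) -> Tensor:
    return _unary(a, np.log(a.data), lambda g: g / a.data)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _unary(a, a.data * mask, lambda g: g * mask)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)
    return _unary(a, out_data, lambda g: g * (1 - out_data**2))


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    return _unary(a, out_data, lambda g: g * out_data * (1 - out_data))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        return y * (g - (g * y).sum(axis=axis, keepdims=True))

    return _unary(a, y, bwd)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
    out_data = x - lse
    sm = np.exp(out_data)

    def bwd(g):
        return g - sm * g.sum(axis=axis, keepdims=True)

    return _unary(a, out_data, bwd)


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data)
    if _GRAD_ENABLED and (a.requires_grad or gain.requires_grad or bias.requires_grad):
        out.requires_grad = True
        out._parents = tuple(p for p in (a, gain, bias) if p.requires_grad)

        def backward(g):
            if gain.requires_grad:
                gain._accumulate(
                    _unbroadcast(g * xhat, gain.data.shape)
                )
            if bias.requires_grad:
                bias._accumulate(_unbroadcast(g, bias.data.shape))
            if a.requires_grad:
                d = a.data.shape[-1]
                gx = g * gain.data
                # standard layer-norm input gradient
                ga = (
                    gx - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                ) * inv
                a._accumulate(ga)

        out._backward = backward
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient into the table."""
    ids = np.asarray(ids)
    out_data = table.data[ids]
    out = Tensor(out_data)
    if _GRAD_ENABLED and table.requires_grad:
        out.requires_grad = True
        out._parents = (table,)

        def backward(g):
            acc = np.zeros_like(table.data)
            np.add.at(acc, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accumulate(acc)

        out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    parents = tuple(t for t in tensors if t.requires_grad)
    if _GRAD_ENABLED and parents:
        out.requires_grad = True
        out._parents = parents
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            pieces = np.split(g, offsets[1:-1], axis=axis)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = backward
    return out
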