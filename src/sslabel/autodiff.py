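"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the package's numerics core: a small define-by-run tape with the
operations the sequence-labeling backbone needs (broadcasting arithmetic,
batched matmul, softmax, layer normalization, 1-D convolution, gathers for
length-aware sequence reversal).  Everything is float64; gradients are
checked against central finite differences in the test suite.

Only what the backbone uses is implemented — this is not a general
framework, and keeping the op set small is what keeps it verifiable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "astensor", "matmul", "concat", "softmax", "layer_norm",
    "conv1d", "gather_rows", "relu", "tanh", "sigmoid", "exp", "log",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation tape.

    ``data`` is a float64 ndarray; ``grad`` is populated by
    :meth:`backward`.  Arithmetic operators build the tape; mixing with
    plain arrays/scalars treats them as constants.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self.grad = None
        self._parents = _parents if self.requires_grad else ()
        self._vjp = _vjp if self.requires_grad else None

    # -- graph mechanics ---------------------------------------------------

    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (typically scalar) node into leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = np.zeros_like(node.data)
            node.grad = node.grad + g
            if node._vjp is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                grads[key] = grads.get(key, 0) + pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = astensor(other)
        return Tensor(
            self.data + other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.data**exponent,
            _parents=(self,),
            _vjp=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        return matmul(self, astensor(other))

    def __rmatmul__(self, other):
        return matmul(astensor(other), self)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _vjp=lambda g: (g.reshape(old),),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            _parents=(self,),
            _vjp=lambda g: (g.transpose(inv),),
        )

    def __getitem__(self, key):
        out = self.data[key]

        def vjp(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return Tensor(out, _parents=(self,), _vjp=vjp)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, self.data.shape).copy(),)

        return Tensor(out, _parents=(self,), _vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities --------------------------------------------


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), _parents=(x,), _vjp=lambda g: (g / x.data,))


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * (1.0 - out**2),))


def sigmoid(x: Tensor) -> Tensor:
    out = 0.5 * (np.tanh(0.5 * x.data) + 1.0)  # numerically stable logistic
    return Tensor(out, _parents=(x,), _vjp=lambda g: (g * out * (1.0 - out),))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, _parents=(x,), _vjp=lambda g: (g * mask,))


# -- linear algebra ---------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with NumPy batching semantics (leading dims broadcast)."""
    out = a.data @ b.data

    def vjp(g):
        if b.data.ndim == 1:
            ga = np.outer(g, b.data) if a.data.ndim > 1 else g * b.data
            gb = a.data.T @ g if a.data.ndim > 1 else g * a.data
            return (_unbroadcast(np.asarray(ga), a.data.shape),
                    _unbroadcast(np.asarray(gb), b.data.shape))
        if a.data.ndim == 1:
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.outer(a.data, g)
            return (_unbroadcast(ga, a.data.shape),
                    _unbroadcast(gb, b.data.shape))
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

    return Tensor(out, _parents=(a, b), _vjp=vjp)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjp=vjp,
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        inner = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - inner),)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then scale+shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gain.data + bias.data
    d = x.data.shape[-1]

    def vjp(g):
        gxhat = g * gain.data
        gx = inv * (
            gxhat
            - gxhat.mean(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True)
        )
        ggain = _unbroadcast(g * xhat, gain.data.shape)
        gbias = _unbroadcast(g, bias.data.shape)
        return (gx, ggain, gbias)

    return Tensor(out, _parents=(x, gain, bias), _vjp=vjp)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-length 1-D convolution along the sequence axis.

    ``x`` is (B, L, C_in); ``weight`` is (k, C_in, C_out) with odd k;
    zero padding of (k-1)/2 on both sides keeps the output length L.
    """
    k = weight.data.shape[0]
    if k % 2 == 0:
        raise ValueError("conv1d requires an odd kernel width")
    pad = k // 2
    B, L, Cin = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    # windows[j] = x shifted by offset j, shape (k, B, L, Cin)
    windows = np.stack([xp[:, j : j + L, :] for j in range(k)])
    out = np.einsum("jblc,jcd->bld", windows, weight.data) + bias.data

    def vjp(g):
        gw = np.einsum("jblc,bld->jcd", windows, g)
        gb = g.sum(axis=(0, 1))
        gxp = np.zeros_like(xp)
        for j in range(k):
            gxp[:, j : j + L, :] += np.einsum("bld,jcd->blc", g, weight.data[j : j + 1])
        gx = gxp[:, pad : pad + L, :]
        return (gx, gw, gb)

    return Tensor(out, _parents=(x, weight, bias), _vjp=vjp)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Per-batch row gather: ``out[b, t] = x[b, index[b, t]]``.

    Used to reverse each sequence within its own true length when
    running the backward direction of a recurrent layer over a padded
    batch.
    """
    index = np.asarray(index)
    B = np.arange(x.data.shape[0])[:, None]
    out = x.data[B, index]

    def vjp(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (B, index), g)
        return (gx,)

    return Tensor(out, _parents=(x,), _vjp=vjp)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return Tensor(x.data * keep, _parents=(x,), _vjp=lambda g: (g * keep,))
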