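"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's sequence models (convolutional, recurrent, attentive-pooling)
are small enough that a tape-based scalar-loss autodiff over float64 arrays
is fast and, importantly, bit-reproducible on CPU. Only the primitives the
model zoo needs are implemented; every op supports NumPy broadcasting with
gradients reduced back to the operand shapes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "concatenate", "maximum", "minimum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # ---------------------------------------------------------------- basics
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.outer(a, g) if b.ndim == 2 else None
                if gb is None:
                    raise NotImplementedError
            elif b.ndim == 1:
                ga = np.multiply.outer(g, b) if a.ndim == 2 else None
                if ga is None:
                    raise NotImplementedError
                gb = np.swapaxes(a, -1, -2) @ g
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, self.shape),
                    _unbroadcast(gb, other.shape))
        out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _parents=(self,))

        def bw(g):
            od = out_data if keepdims else np.expand_dims(out_data, axis)
            mask = (self.data == od)
            # split gradient evenly across ties for determinism
            counts = mask.sum(axis=axis, keepdims=True)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (mask * (gg / counts),)
        out._backward = bw
        return out

    # ---------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: (g * 0.5 / val,)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: (g * (1.0 - val ** 2),)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, _parents=(self,))
        out._backward = lambda g: (g * val * (1.0 - val),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    # --------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bw(g):
            full = np.zeros(self.shape)
            np.add.at(full, key, g)
            return (full,)
        out._backward = bw
        return out

    def take_time(self, idx: np.ndarray):
        """Gather along the last axis with an integer index array.

        Used by the im2col convolution: for input (..., T) and idx of shape
        (T_out, K) returns (..., T_out, K); repeated indices accumulate
        gradient, which plain fancy indexing via __getitem__ also handles
        but this variant avoids building a full-rank index tuple.
        """
        out = Tensor(self.data[..., idx], _parents=(self,))

        def bw(g):
            # C-ordered buffer so the reshape below is a view, not a copy
            full = np.zeros(self.shape)
            np.add.at(full.reshape(-1, self.shape[-1]),
                      (slice(None), idx),
                      np.ascontiguousarray(g).reshape(-1, *idx.shape))
            return (full,)
        out._backward = bw
        return out

    # ------------------------------------------------------------- softmax
    def log_softmax(self, axis: int = -1):
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shift - shift.exp().sum(axis=axis, keepdims=True).log()

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # ------------------------------------------------------------- backward
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        # reset intermediate grads so repeated backward calls on one graph
        # stay independent; leaf tensors keep accumulation semantics
        for node in topo:
            if node._parents:
                node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))
    out._backward = bw
    return out


def maximum(t: Tensor, const: float) -> Tensor:
    """Elementwise max against a constant (clips from below)."""
    t = astensor(t)
    mask = t.data > const
    out = Tensor(np.maximum(t.data, const), _parents=(t,))
    out._backward = lambda g: (g * mask,)
    return out


def minimum(t: Tensor, const: float) -> Tensor:
    t = astensor(t)
    mask = t.data < const
    out = Tensor(np.minimum(t.data, const), _parents=(t,))
    out._backward = lambda g: (g * mask,)
    return out
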