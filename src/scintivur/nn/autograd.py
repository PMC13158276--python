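"""Minimal reverse-mode automatic differentiation over numpy arrays.

A `Tensor` wraps an ndarray and records the operations that produced it;
`backward()` walks the graph in reverse topological order accumulating
gradients. The op set is exactly what the windowed-attention classifier
needs (broadcasted arithmetic, matmul, reshape/transpose/slicing, softmax,
reductions, sigmoid/gelu, stride-1 convolution, embedding-style take).
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "concatenate", "conv2d", "default_dtype", "get_default_dtype"]

_DEFAULT_DTYPE = np.dtype(np.float64)


def get_default_dtype() -> np.dtype:
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype new tensors are created with.

    float64 (the default) is used for gradient checking and exact oracles;
    float32 roughly halves training time on CPU.
    """
    global _DEFAULT_DTYPE
    previous = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DEFAULT_DTYPE = previous


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
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


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g, self.shape),
            _unbroadcast(g, other.shape),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g * other.data, self.shape),
            _unbroadcast(g * self.data, other.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        out._backward = lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / other.data**2, other.shape),
        )
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        out._backward = backward
        return out

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: (g * (1.0 - y**2),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)
        out = Tensor(y, parents=(self,))

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            return (g * dy,)

        out._backward = backward
        return out

    def sqrt(self):
        return self**0.5

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))
        parts = key if isinstance(key, tuple) else (key,)
        basic = all(isinstance(k, (int, slice, type(None), type(Ellipsis))) for k in parts)

        def backward(g):
            gp = np.zeros(self.shape, dtype=self.data.dtype)
            if basic:  # views cannot alias, so a plain in-place add is exact
                gp[key] += g
            else:
                np.add.at(gp, key, g)
            return (gp,)

        out._backward = backward
        return out

    def take(self, index: np.ndarray):
        """Gather rows of a 2-D table by an integer index array."""
        index = np.asarray(index)
        out = Tensor(self.data[index], parents=(self,))

        def backward(g):
            gp = np.zeros(self.shape, dtype=self.data.dtype)
            np.add.at(gp, index, g)
            return (gp,)

        out._backward = backward
        return out

    def pad2d(self, pad_h: tuple[int, int], pad_w: tuple[int, int], value: float = 0.0):
        """Constant-pad the last two axes."""
        width = [(0, 0)] * (self.ndim - 2) + [pad_h, pad_w]
        out = Tensor(np.pad(self.data, width, constant_values=value), parents=(self,))
        sl = tuple(
            [slice(None)] * (self.ndim - 2)
            + [
                slice(pad_h[0], out.shape[-2] - pad_h[1]),
                slice(pad_w[0], out.shape[-1] - pad_w[1]),
            ]
        )
        out._backward = lambda g: (g[sl],)
        return out

    def roll(self, shift: tuple[int, ...], axis: tuple[int, ...]):
        out = Tensor(np.roll(self.data, shift, axis=axis), parents=(self,))
        neg = tuple(-s for s in shift)
        out._backward = lambda g: (np.roll(g, neg, axis=axis),)
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        y = self.data.max(axis=axis, keepdims=True)
        mask = self.data == y
        # route the gradient to the first maximiser along the axis
        first = np.cumsum(mask, axis=axis) == 1
        mask = mask & first
        out = Tensor(y if keepdims else np.squeeze(y, axis=axis), parents=(self,))

        def backward(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (mask * g2,)

        out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        out._backward = backward
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concatenate(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = backward
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2-D cross-correlation, NCHW layout.

    x: (N, C, H, W); weight: (O, C, kh, kw); bias: (O,). Used for the 7x7
    spatial-attention convolution and the 1x1 recalibration convolution.
    """
    kh, kw = weight.shape[-2:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # windows: (N, C, Hout, Wout, kh, kw)
    y = np.einsum("nchwij,ocij->nohw", windows, weight.data, optimize=True)
    if bias is not None:
        y = y + bias.data[None, :, None, None]
        parents = (x, weight, bias)
    else:
        parents = (x, weight)
    out = Tensor(y, parents=parents)
    hout, wout = y.shape[-2:]

    def backward(g):
        gw = np.einsum("nchwij,nohw->ocij", windows, g, optimize=True)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + hout, j : j + wout] += np.einsum(
                    "nohw,oc->nchw", g, weight.data[:, :, i, j], optimize=True
                )
        gx = gxp[:, :, padding : xp.shape[2] - padding or None, padding : xp.shape[3] - padding or None]
        if bias is not None:
            return gx, gw, g.sum(axis=(0, 2, 3))
        return gx, gw

    out._backward = backward
    return out
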