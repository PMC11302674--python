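"""Compact reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the temporal convolutional
networks and variational objectives in this package: broadcasting
elementwise arithmetic, (batched) matmul, reductions, basic slicing,
zero padding, and the usual pointwise nonlinearities.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` in reverse
topological order.

Dtype is preserved: float32 graphs stay float32 (used for network
training), float64 graphs stay float64 (used where tests need tight
numerical agreement).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "log_softmax", "softmax", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` dispatch to the reflected Tensor op
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        else:
            out._parents = ()
            out._backward = None
        return out

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

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g / b.data, a.data.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(a.data ** p, (a,),
                            lambda g: (g * p * a.data ** (p - 1),))

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        out = a.data @ b.data

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)
            return ga, gb

        return Tensor._make(out, (a, b), backward)

    # -- pointwise ----------------------------------------------------------
    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: (g * out,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return Tensor._make(out, (a,), lambda g: (g / (2.0 * out),))

    def tanh(self):
        a = self
        out = np.tanh(a.data)
        return Tensor._make(out, (a,), lambda g: (g * (1.0 - out ** 2),))

    def leaky_relu(self, alpha: float = 0.01):
        a = self
        pos = a.data > 0
        scale = np.where(pos, 1.0, alpha).astype(a.data.dtype)
        return Tensor._make(a.data * scale, (a,), lambda g: (g * scale,))

    def astype(self, dtype):
        """Cast values; the gradient is cast back to the input dtype."""
        a = self
        dtype = np.dtype(dtype)
        old = a.data.dtype
        return Tensor._make(a.data.astype(dtype), (a,),
                            lambda g: (g.astype(old),))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where values are inside [lo, hi]."""
        a = self
        inside = ((a.data >= lo) & (a.data <= hi)).astype(a.data.dtype)
        return Tensor._make(np.clip(a.data, lo, hi), (a,), lambda g: (g * inside,))

    # -- reductions / shaping -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.data.shape).astype(a.data.dtype, copy=False),)

        return Tensor._make(np.asarray(out), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = a.data.shape
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: (g.reshape(old),))

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,),
                            lambda g: (np.swapaxes(g, ax1, ax2),))

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            full[idx] += g
            return (full,)

        return Tensor._make(a.data[idx], (a,), backward)

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad along one axis."""
        a = self
        pad = [(0, 0)] * a.data.ndim
        pad[axis] = (before, after)
        sl = [slice(None)] * a.data.ndim
        n = a.data.shape[axis]
        sl[axis] = slice(before, before + n)
        sl = tuple(sl)
        return Tensor._make(np.pad(a.data, pad), (a,), lambda g: (g[sl],))

    # -- backward -----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg


# -- free functions ----------------------------------------------------------

def dilated_conv1d(x: Tensor, w: Tensor, b: Tensor, lags: int,
                   dilation: int) -> Tensor:
    """Symmetric dilated 1-D convolution over (B, T, Cin) input.

    `w` has shape (2*lags+1, Cin, Cout); the time axis is zero-padded by
    lags*dilation on each side so T is preserved.  Fused into one matmul
    over stacked taps for speed; gradients are computed in closed form.
    """
    x, w, b = Tensor._coerce(x), Tensor._coerce(w), Tensor._coerce(b)
    B, T, Cin = x.data.shape
    width = 2 * lags + 1
    Cout = w.data.shape[2]
    pad = lags * dilation
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    xw = np.concatenate([xp[:, j * dilation:j * dilation + T, :]
                         for j in range(width)], axis=2)  # (B, T, width*Cin)
    w2 = w.data.reshape(width * Cin, Cout)
    out = xw.reshape(B * T, width * Cin) @ w2
    out = out.reshape(B, T, Cout) + b.data

    def backward(g):
        g2 = g.reshape(B * T, Cout)
        gw = (xw.reshape(B * T, width * Cin).T @ g2).reshape(w.data.shape)
        gb = g.sum(axis=(0, 1))
        gxw = (g2 @ w2.T).reshape(B, T, width * Cin)
        gxp = np.zeros_like(xp)
        for j in range(width):
            gxp[:, j * dilation:j * dilation + T, :] += \
                gxw[:, :, j * Cin:(j + 1) * Cin]
        return gxp[:, pad:pad + T, :], gw, gb

    return Tensor._make(out, (x, w, b), backward)

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            outs.append(g[tuple(sl)])
        return tuple(outs)

    return Tensor._make(data, tuple(tensors), backward)


def logsumexp(t: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = Tensor(np.max(t.data, axis=axis, keepdims=True))  # constant shift
    s = (t - m).exp().sum(axis=axis, keepdims=True).log() + m
    if not keepdims:
        s = s.reshape(tuple(np.delete(np.array(s.shape), axis)))
    return s


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    return t - logsumexp(t, axis=axis, keepdims=True)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(t, axis=axis).exp()
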