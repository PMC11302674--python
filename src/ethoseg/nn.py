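"""Neural-network building blocks on top of the autodiff core.

Layers operate on time-major batches shaped ``(B, T, channels)``.  The
central component is :class:`DilatedTCN`, a symmetric (non-causal)
dilated temporal convolutional stack: dilation blocks of
conv -> leaky ReLU -> dropout sub-layers with a residual connection per
block and dilation doubling between blocks.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

DEFAULT_DTYPE = np.float32


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype)


def _uniform(rng: np.random.Generator, shape, fan_in: int, dtype=DEFAULT_DTYPE):
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Module):
    """Affine map applied to the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        self.weight = Parameter(_uniform(rng, (in_dim, out_dim), in_dim, dtype))
        self.bias = Parameter(_uniform(rng, (out_dim,), in_dim, dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Dilated 1-D convolution over the time axis of (B, T, Cin) input.

    Symmetric kernel of half-width `lags` (width 2*lags+1); the sequence
    is zero-padded by lags*dilation on each side so T is preserved.
    """

    def __init__(self, in_dim: int, out_dim: int, lags: int, dilation: int,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        self.lags = lags
        self.dilation = dilation
        width = 2 * lags + 1
        fan_in = in_dim * width
        self.weight = Parameter(_uniform(rng, (width, in_dim, out_dim), fan_in, dtype))
        self.bias = Parameter(_uniform(rng, (out_dim,), fan_in, dtype))

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import dilated_conv1d
        return dilated_conv1d(x, self.weight, self.bias, self.lags, self.dilation)


class Dropout(Module):
    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator | None) -> Tensor:
        if not train or self.p <= 0.0:
            return x
        keep = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return x * keep


class DilatedTCN(Module):
    """Dilation blocks of (conv -> leaky ReLU -> dropout) sub-layers with a
    per-block residual connection, followed by a width-1 linear head.

    Block b (1-indexed) uses dilation 2**(b-1).  When block input and
    output widths differ, the residual uses a learned width-1 projection.
    The head applies no nonlinearity: logits / Gaussian parameters are
    consumed downstream.
    """

    def __init__(self, in_dim: int, out_dim: int, n_blocks: int = 2,
                 n_sublayers: int = 2, lags: int = 4, n_filters: int = 32,
                 dropout_p: float = 0.10, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.blocks = []
        self.residuals = []
        cin = in_dim
        for b in range(n_blocks):
            dilation = 2 ** b
            convs = []
            c = cin
            for _ in range(n_sublayers):
                convs.append(Conv1d(c, n_filters, lags, dilation, rng))
                c = n_filters
            self.blocks.append(convs)
            self.residuals.append(Linear(cin, n_filters, rng) if cin != n_filters else None)
            cin = n_filters
        self.dropout = Dropout(dropout_p)
        self.head = Linear(cin, out_dim, rng)

    def parameters(self):
        params = []
        for convs in self.blocks:
            for conv in convs:
                params.extend(conv.parameters())
        for res in self.residuals:
            if res is not None:
                params.extend(res.parameters())
        params.extend(self.head.parameters())
        return params

    def __call__(self, x: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = x
        for convs, res in zip(self.blocks, self.residuals):
            block_in = h
            for conv in convs:
                h = self.dropout(conv(h).leaky_relu(), train, rng)
            shortcut = res(block_in) if res is not None else block_in
            h = h + shortcut
        return self.head(h)


class MLP(Module):
    """One-hidden-layer dense network with tanh hidden units."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        self.lin1 = Linear(in_dim, hidden, rng, dtype)
        self.lin2 = Linear(hidden, out_dim, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).tanh())

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        h = np.tanh(x @ self.lin1.weight.data + self.lin1.bias.data)
        return h @ self.lin2.weight.data + self.lin2.bias.data


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of Parameters."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
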