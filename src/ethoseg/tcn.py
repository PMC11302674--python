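"""Dilated TCN backbone configuration and receptive-field arithmetic.

The backbone used by the supervised classifier and by both amortized
posterior networks: dilation blocks of symmetric dilated convolutions
(kernel half-width = `temporal_lags`, so kernel width 2*lags+1), with
dilation 2**(b-1) in block b.  The output at frame t therefore depends
on input frames {t-tau, ..., t+tau} with

    tau = temporal_lags * n_sublayers_per_block * sum_b 2**(b-1).

With the default configuration (2 blocks, 2 sub-layers, 4 lags) this
gives tau = 24, i.e. a 49-frame window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .features import FeatureSequence
from .nn import DilatedTCN


@dataclass
class TCNConfig:
    in_dim: int = 1
    out_dim: int = 1
    n_blocks: int = 2
    n_sublayers_per_block: int = 2
    temporal_lags: int = 4
    n_filters: int = 32
    dropout_p: float = 0.10

    def __post_init__(self):
        for name in ("in_dim", "out_dim", "n_blocks", "n_sublayers_per_block",
                     "temporal_lags", "n_filters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")

    @property
    def kernel_width(self) -> int:
        return 2 * self.temporal_lags + 1

    def dilation(self, block: int) -> int:
        """Dilation of 1-indexed block b: 2**(b-1)."""
        return 2 ** (block - 1)


def receptive_field_half_width(cfg: TCNConfig) -> int:
    """Half-width tau of the output receptive field, in frames."""
    total_dilation = sum(cfg.dilation(b) for b in range(1, cfg.n_blocks + 1))
    return cfg.temporal_lags * cfg.n_sublayers_per_block * total_dilation


def window_duration_s(cfg: TCNConfig, frame_rate_hz: float) -> float:
    """Duration of the (2 tau + 1)-frame receptive-field window in seconds."""
    return (2 * receptive_field_half_width(cfg) + 1) / frame_rate_hz


def build_tcn(cfg: TCNConfig, rng: np.random.Generator | None = None) -> DilatedTCN:
    return DilatedTCN(cfg.in_dim, cfg.out_dim, n_blocks=cfg.n_blocks,
                      n_sublayers=cfg.n_sublayers_per_block,
                      lags=cfg.temporal_lags, n_filters=cfg.n_filters,
                      dropout_p=cfg.dropout_p, rng=rng)


def tcn_forward(cfg: TCNConfig, network: DilatedTCN, fs: FeatureSequence) -> np.ndarray:
    """Evaluate the network on one session (evaluation mode, no dropout).

    Returns a T x out_dim array; row t depends only on input rows in
    {t-tau, ..., t+tau} with zero padding at sequence edges.
    """
    if fs.n_features != cfg.in_dim:
        raise ValueError(f"feature dim {fs.n_features} != in_dim {cfg.in_dim}")
    x = Tensor(fs.values[None].astype(np.float32))
    return np.asarray(network(x, train=False).data[0], dtype=np.float64)
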