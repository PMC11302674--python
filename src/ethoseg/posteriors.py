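"""Amortized approximate posteriors.

The variational family factorizes per frame as

    q(y_t, z_t | x_Tt) = q(y_t | x_Tt) q(z_t | x_Tt, y_t)

with x_Tt a receptive-field window of observations centered at frame t.
``q(y_t | x_Tt)`` is a softmax classifier head; ``q(z_t | x_Tt, y_t=k)``
is a diagonal Gaussian whose (mu, log var) come from K parallel output
heads on a shared trunk, so all class-conditional encoders are evaluated
in one pass (the unlabeled bound sums over k).  Two separate backbones
are used, one per posterior factor.

Temporal variants use the dilated TCN backbone; static variants replace
it with a per-frame one-hidden-layer dense network, which is the
inference-side ablation used by the static mixture model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, log_softmax
from .features import FeatureSequence
from .nn import MLP, Module
from .tcn import TCNConfig, build_tcn

LOGVAR_CLAMP = 10.0  # log-variance heads are clamped to [-10, 10]


@dataclass
class PosteriorFactors:
    """Per-frame classifier simplex and class-conditional Gaussian parameters.

    Arrays carry a leading batch axis: class_probs (B, T, K),
    z_mean / z_logvar (B, T, K, Dz).
    """

    class_probs: Tensor
    log_class_probs: Tensor
    z_mean: Tensor
    z_logvar: Tensor

    @property
    def K(self) -> int:
        return self.class_probs.shape[-1]

    @property
    def Dz(self) -> int:
        return self.z_mean.shape[-1]

    def sample_z(self, rng: np.random.Generator, n_draws: int | None = None) -> Tensor:
        """Reparameterized draws z = mu + sigma * eps, one per (frame, class).

        With `n_draws` the epsilon gets an extra leading sample axis.
        """
        shape = self.z_mean.shape if n_draws is None else (n_draws,) + self.z_mean.shape
        eps = rng.standard_normal(shape).astype(self.z_mean.data.dtype)
        sigma = (self.z_logvar * 0.5).exp()
        return self.z_mean + sigma * eps

    @staticmethod
    def from_arrays(class_probs, z_mean, z_logvar) -> "PosteriorFactors":
        cp = Tensor(np.asarray(class_probs, dtype=np.float64))
        log_cp = Tensor(np.log(np.maximum(cp.data, 1e-300)))
        return PosteriorFactors(cp, log_cp, Tensor(np.asarray(z_mean, dtype=np.float64)),
                                Tensor(np.asarray(z_logvar, dtype=np.float64)))


class StaticNet(Module):
    """Per-frame one-hidden-layer dense network (no temporal context)."""

    def __init__(self, in_dim: int, out_dim: int, hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.net = MLP(in_dim, hidden, out_dim, rng, dtype=np.float32)
        self.in_dim = in_dim
        self.out_dim = out_dim

    def __call__(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        return self.net(x)


class AmortizedPosterior(Module):
    """Classifier + class-conditional encoder over a shared input space.

    `temporal=True` uses two dilated TCN backbones (one per factor, as in
    the switching model); `temporal=False` uses per-frame dense networks
    (the static ablation).
    """

    def __init__(self, in_dim: int, K: int, Dz: int,
                 tcn_config: TCNConfig | None = None, temporal: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.K = K
        self.Dz = Dz
        self.temporal = temporal
        if temporal:
            base = tcn_config or TCNConfig()
            self.classifier_cfg = TCNConfig(
                in_dim=in_dim, out_dim=K, n_blocks=base.n_blocks,
                n_sublayers_per_block=base.n_sublayers_per_block,
                temporal_lags=base.temporal_lags, n_filters=base.n_filters,
                dropout_p=base.dropout_p)
            self.encoder_cfg = TCNConfig(
                in_dim=in_dim, out_dim=K * 2 * Dz, n_blocks=base.n_blocks,
                n_sublayers_per_block=base.n_sublayers_per_block,
                temporal_lags=base.temporal_lags, n_filters=base.n_filters,
                dropout_p=base.dropout_p)
            self.classifier = build_tcn(self.classifier_cfg, rng)
            self.encoder = build_tcn(self.encoder_cfg, rng)
        else:
            self.classifier = StaticNet(in_dim, K, rng=rng)
            self.encoder = StaticNet(in_dim, K * 2 * Dz, rng=rng)

    def parameters(self):
        return self.classifier.parameters() + self.encoder.parameters()

    def __call__(self, x, train: bool = False,
                 rng: np.random.Generator | None = None) -> PosteriorFactors:
        """Evaluate both factors on a (B, T, D) batch (arrays or Tensor)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 3 or x.shape[-1] != self.in_dim:
            raise ValueError(f"expected (B, T, {self.in_dim}) input, got {x.shape}")
        B, T = x.shape[0], x.shape[1]
        logits = self.classifier(x, train=train, rng=rng).astype(np.float64)
        log_probs = log_softmax(logits, axis=-1)
        enc = self.encoder(x, train=train, rng=rng).astype(np.float64)
        enc = enc.reshape(B, T, self.K, 2 * self.Dz)
        z_mean = enc[..., :self.Dz]
        z_logvar = enc[..., self.Dz:].clip(-LOGVAR_CLAMP, LOGVAR_CLAMP)
        return PosteriorFactors(log_probs.exp(), log_probs, z_mean, z_logvar)


# -- convenience operations ---------------------------------------------------

def classify(posterior: AmortizedPosterior, fs: FeatureSequence) -> np.ndarray:
    """Per-frame class probabilities q(y_t | x_Tt); rows sum to 1."""
    factors = posterior(fs.values[None].astype(np.float32))
    return np.asarray(factors.class_probs.data[0], dtype=np.float64)


def encode_z(posterior: AmortizedPosterior, fs: FeatureSequence,
             y_weights: np.ndarray | None = None, seed: int = 0):
    """Class-conditional Gaussian parameters and one reparameterized draw.

    Returns (z_mean, z_logvar, z_sample) each shaped (T, K, Dz); when
    `y_weights` rows are given (simplices or one-hot observed labels) a
    weight-averaged sample of shape (T, Dz) is returned as a fourth item.
    """
    factors = posterior(fs.values[None].astype(np.float32))
    rng = np.random.default_rng(seed)
    z = factors.sample_z(rng)
    mu = np.asarray(factors.z_mean.data[0], dtype=np.float64)
    logvar = np.asarray(factors.z_logvar.data[0], dtype=np.float64)
    z0 = np.asarray(z.data[0], dtype=np.float64)
    if y_weights is None:
        return mu, logvar, z0
    w = np.asarray(y_weights, dtype=np.float64)
    return mu, logvar, z0, (w[..., None] * z0).sum(axis=1)
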