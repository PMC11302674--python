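"""Variational objectives for the switching and static generative models.

Three bounds are implemented:

* ``labeled_elbo``  — the lower bound with every frame's discrete state
  observed: reconstruction, an initial-frame KL to the N(0, I) prior, a
  per-frame dynamics KL against the state-conditional latent dynamics,
  and the discrete log prior / transition log-probabilities.
* ``unlabeled_elbo`` — the fully unobserved bound, in which every term is
  weighted by the classifier posterior q(y_t | x_Tt); the dynamics KL
  couples consecutive frames through a K x K sum and the transition term
  becomes a categorical KL against the recurrent transition distribution.
* ``semisupervised_loss`` — the mixed bound: the discrete weights r(y_t)
  are the classifier rows on unlabeled frames and one-hot vectors on
  labeled frames, plus an alpha-weighted, class-weighted cross-entropy
  classification term over the labeled frames.

Each term of the unlabeled bound reduces exactly to the corresponding
labeled term under one-hot weights with shared reparameterized samples;
``labeled_elbo`` is coded as an independent transcription of the labeled
bound so this reduction is a real (and tested) identity rather than a
tautology.

A single reparameterized sample per (frame, class) is used per
evaluation; the transition and dynamics terms at frame t reuse the
samples already drawn for frame t-1.  KL terms (and the discrete
log-prior terms they absorb) are multiplied by the annealing weight;
reconstruction and classification never are.

The static-model bound (``gmdgm_elbo``) drops all temporal terms: the
unlabeled part decomposes as sum_k q(y=k|x) L_l(x, k) + H(q(y|x)), with
the entropy entering with a plus sign, equivalently a -KL(r || pi)
categorical term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, log_softmax
from .features import LabelSequence
from .generative import GMDGMParams, RSLDSParams
from .posteriors import PosteriorFactors

_LOG2PI = float(np.log(2.0 * np.pi))
_EPS = 1e-12


@dataclass
class LossConfig:
    alpha: float = 100.0
    anneal_epochs: int = 100
    class_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.anneal_epochs < 1:
            raise ValueError("anneal_epochs must be positive")
        if self.class_weights is not None:
            self.class_weights = np.asarray(self.class_weights, dtype=np.float64)
            if not np.all(np.isfinite(self.class_weights)):
                raise ValueError("class_weights must be finite")


@dataclass
class ObjectiveTerms:
    """Itemized bound components (autodiff scalars) and their combination.

    total = recon - anneal_w * (kl_z_init + kl_z_dyn + kl_y_init + kl_y_trans)
            + alpha * classification
    """

    recon: Tensor
    kl_z_init: Tensor
    kl_z_dyn: Tensor
    kl_y_init: Tensor
    kl_y_trans: Tensor
    classification: Tensor
    alpha: float = 0.0
    anneal_w: float = 1.0
    total: Tensor = field(init=False)

    def __post_init__(self):
        kl = self.kl_z_init + self.kl_z_dyn + self.kl_y_init + self.kl_y_trans
        self.total = (self.recon - self.anneal_w * kl
                      + self.alpha * self.classification)

    @property
    def elbo(self) -> Tensor:
        """Un-annealed bound without the classification term."""
        return (self.recon - self.kl_z_init - self.kl_z_dyn
                - self.kl_y_init - self.kl_y_trans)

    def as_floats(self) -> dict:
        out = {}
        for name in ("recon", "kl_z_init", "kl_z_dyn", "kl_y_init",
                     "kl_y_trans", "classification", "total"):
            val = getattr(self, name).data
            out[name] = float(val) if val.ndim == 0 else float(np.mean(val))
        return out


# -- closed-form divergences (public plumbing) --------------------------------

def gaussian_kl_diag(mu_q, var_q, mu_p, var_p) -> float:
    """KL between diagonal Gaussians, summed over dimensions."""
    mu_q, var_q = np.asarray(mu_q, float), np.asarray(var_q, float)
    mu_p, var_p = np.asarray(mu_p, float), np.asarray(var_p, float)
    if np.any(var_q <= 0) or np.any(var_p <= 0):
        raise ValueError("variances must be positive")
    return float(0.5 * np.sum(np.log(var_p / var_q)
                              + (var_q + (mu_q - mu_p) ** 2) / var_p - 1.0))


def categorical_kl(q, p) -> float:
    """KL between categorical distributions; 0 log 0 = 0, support mismatch
    yields +inf."""
    q, p = np.asarray(q, float), np.asarray(p, float)
    for v in (q, p):
        if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("inputs must be simplices")
    if np.any((p == 0) & (q > 0)):
        return float("inf")
    mask = q > 0
    return float(np.sum(q[mask] * np.log(q[mask] / p[mask])))


# -- tensor helpers -----------------------------------------------------------

def _diag_logpdf_t(x, mean: Tensor, logvar: Tensor) -> Tensor:
    """Elementwise log N(x; mean, exp(logvar)) summed over the last axis."""
    diff = mean - x if isinstance(mean, Tensor) else Tensor(x) - mean
    return (-0.5 * (_LOG2PI + logvar + diff * diff * (-logvar).exp())).sum(axis=-1)


def _kl_diag_t(mu_q: Tensor, logvar_q: Tensor, mu_p, logvar_p) -> Tensor:
    diff = mu_q - mu_p
    return (0.5 * (logvar_p - logvar_q
                   + (logvar_q - logvar_p).exp()
                   + diff * diff * (-logvar_p if isinstance(logvar_p, Tensor)
                                    else Tensor(-np.asarray(logvar_p))).exp()
                   - 1.0)).sum(axis=-1)


def _as_batched_x(x) -> np.ndarray:
    x = np.asarray(getattr(x, "values", x), dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    return x


def _one_hot(labels: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros(labels.shape + (K,), dtype=np.float64)
    valid = labels >= 0
    out[(*np.nonzero(valid), labels[valid])] = 1.0
    return out


def _xlogx(r: Tensor) -> Tensor:
    return r * (r + _EPS).log()


# -- switching-model bounds ---------------------------------------------------

def _weighted_terms(params: RSLDSParams, post: PosteriorFactors,
                    x: np.ndarray, r: Tensor, z: Tensor) -> dict:
    """All Eq-38-style terms for discrete weights r (B, T, K) and shared
    reparameterized samples z ((S,) B, T, K, Dz).  Every returned term has
    shape (S,) if a sample axis is present (scalar otherwise) except the
    analytic KLs, which are sample-free scalars."""
    B, T, K = r.shape
    log_pi = log_softmax(params.pi0_logits, axis=-1)

    # reconstruction: sum_t sum_k r_tk log N(x_t; g(z_tk), S)
    mean = params.emission_mean_t(z)                      # (..., B, T, K, Dx)
    logp_x = _diag_logpdf_t(x[:, :, None, :], mean, params.emission_logS)
    recon = (r * logp_x).sum(axis=(-3, -2, -1))

    # initial-frame latent KL: sum_k r_1k KL(q(z_1|k) || N(0, I))
    kl0 = _kl_diag_t(post.z_mean[:, 0], post.z_logvar[:, 0],
                     np.zeros(params.Dz), np.zeros(params.Dz))  # (B, K)
    kl_z_init = (r[:, 0, :] * kl0).sum()

    # initial-frame categorical KL: KL(r(y_1) || pi)
    kl_y_init = (_xlogx(r[:, 0, :]) - r[:, 0, :] * log_pi).sum()

    kl_z_dyn = None
    kl_y_trans = None
    if T > 1:
        z_prev = z[..., :-1, :, :]                        # (..., B, T-1, K', Dz)
        r_prev = r[:, :-1, :]                             # (B, T-1, K')
        r_curr = r[:, 1:, :]                              # (B, T-1, K)
        log_r_curr = (r_curr + _EPS).log()
        for k in range(K):
            # dynamics KL against N(A_k z_prev^{k'} + b_k, Q_k), all k'
            mu_p = params.dynamics_mean_t(k, z_prev)      # (..., B, T-1, K', Dz)
            kl = _kl_diag_t(post.z_mean[:, 1:, k, None, :],
                            post.z_logvar[:, 1:, k, None, :],
                            mu_p, params.dyn_logQ[k])     # (..., B, T-1, K')
            w = r_curr[:, :, k, None] * r_prev            # (B, T-1, K')
            term = (w * kl).sum(axis=(-3, -2, -1))
            kl_z_dyn = term if kl_z_dyn is None else kl_z_dyn + term
            # transition KL against p(y_t | y_{t-1}=k, z_prev^k)
            logits = params.transition_logits_t(k, z[..., :-1, k, :])
            logp_y = log_softmax(logits, axis=-1)         # (..., B, T-1, K)
            kl_y = (r_curr * (log_r_curr - logp_y)).sum(axis=-1)  # (..., B, T-1)
            term = (r_prev[:, :, k] * kl_y).sum(axis=(-2, -1))
            kl_y_trans = term if kl_y_trans is None else kl_y_trans + term
    else:
        kl_z_dyn = Tensor(0.0)
        kl_y_trans = Tensor(0.0)
    return dict(recon=recon, kl_z_init=kl_z_init, kl_z_dyn=kl_z_dyn,
                kl_y_init=kl_y_init, kl_y_trans=kl_y_trans)


def labeled_elbo(params: RSLDSParams, post: PosteriorFactors, x,
                 labels: np.ndarray, seed: int = 0,
                 z: Tensor | None = None) -> ObjectiveTerms:
    """Bound with every frame's discrete state observed.

    Independent transcription of the fully labeled bound: discrete terms
    appear as log-probabilities of the observed states, and only the
    observed-state encoder head enters each Gaussian term.  Samples are
    drawn with `seed` so they can be shared with the unlabeled bound.
    """
    x = _as_batched_x(x)
    labels = np.atleast_2d(np.asarray(labels, dtype=np.int64))
    if np.any(labels < 0):
        raise ValueError("unlabeled frame present in fully labeled bound")
    B, T = labels.shape
    K, Dz = params.K, params.Dz
    if z is None:
        z = post.sample_z(np.random.default_rng(seed))
    onehot = _one_hot(labels, K)                          # (B, T, K)
    sel = lambda arr: (arr * onehot[..., None]).sum(axis=-2)
    mu_q = sel(post.z_mean)                               # (B, T, Dz)
    logvar_q = sel(post.z_logvar)
    z_sel = (z * onehot[..., None]).sum(axis=-2)          # (..., B, T, Dz)

    recon = _diag_logpdf_t(x, params.emission_mean_t(z_sel),
                           params.emission_logS).sum(axis=(-2, -1))
    kl_z_init = _kl_diag_t(mu_q[:, 0], logvar_q[:, 0],
                           np.zeros(Dz), np.zeros(Dz)).sum()
    log_pi = log_softmax(params.pi0_logits, axis=-1)
    kl_y_init = -(onehot[:, 0, :] * log_pi).sum()         # = -log pi_{y_1}

    if T > 1:
        z_prev = z_sel[..., :-1, :]                       # (..., B, T-1, Dz)
        mu_p, logits = None, None
        for k in range(K):
            mk = params.dynamics_mean_t(k, z_prev)
            wk = onehot[:, 1:, k, None]
            mu_p = mk * wk if mu_p is None else mu_p + mk * wk
            lk = log_softmax(params.transition_logits_t(k, z_prev), axis=-1)
            wprev = onehot[:, :-1, k, None]
            logits = lk * wprev if logits is None else logits + lk * wprev
        logQ = (params.dyn_logQ * Tensor(onehot[:, 1:, :, None])).sum(axis=-2)
        kl_z_dyn = _kl_diag_t(mu_q[:, 1:], logvar_q[:, 1:], mu_p, logQ).sum()
        kl_y_trans = -(logits * onehot[:, 1:, :]).sum(axis=(-3, -2, -1))
    else:
        kl_z_dyn = Tensor(0.0)
        kl_y_trans = Tensor(0.0)
    zero = Tensor(0.0)
    return ObjectiveTerms(recon, kl_z_init, kl_z_dyn, kl_y_init, kl_y_trans,
                          classification=zero, alpha=0.0, anneal_w=1.0)


def unlabeled_elbo(params: RSLDSParams, post: PosteriorFactors, x,
                   seed: int = 0, z: Tensor | None = None,
                   n_draws: int | None = None) -> ObjectiveTerms:
    """Bound with every frame's discrete state unobserved (weights are the
    classifier posterior rows)."""
    x = _as_batched_x(x)
    if z is None:
        z = post.sample_z(np.random.default_rng(seed), n_draws=n_draws)
    terms = _weighted_terms(params, post, x, post.class_probs, z)
    return ObjectiveTerms(classification=Tensor(0.0), alpha=0.0, anneal_w=1.0,
                          **terms)


def semisupervised_loss(params: RSLDSParams, post: PosteriorFactors, x,
                        labels, cfg: LossConfig, anneal_w: float = 1.0,
                        seed: int = 0) -> ObjectiveTerms:
    """Mixed bound: one-hot weights on labeled frames, classifier rows on
    unlabeled ones, plus the alpha-weighted classification term."""
    x = _as_batched_x(x)
    if isinstance(labels, LabelSequence):
        labels = labels.labels
    labels = np.atleast_2d(np.asarray(labels, dtype=np.int64))
    B, T = labels.shape
    K = params.K
    labeled = (labels >= 0).astype(np.float64)[..., None]       # (B, T, 1)
    onehot = _one_hot(labels, K)
    r = post.class_probs * (1.0 - labeled) + Tensor(onehot * labeled)
    z = post.sample_z(np.random.default_rng(seed))
    terms = _weighted_terms(params, post, x, r, z)

    weights = (np.ones(K) if cfg.class_weights is None
               else np.asarray(cfg.class_weights, float))
    w_frame = (onehot * weights).sum(axis=-1) * labeled[..., 0]  # (B, T)
    classification = (post.log_class_probs * Tensor(onehot * labeled)
                      ).sum(axis=-1)
    classification = (classification * w_frame).sum()
    return ObjectiveTerms(classification=classification, alpha=cfg.alpha,
                          anneal_w=anneal_w, **terms)


# -- static-model bound -------------------------------------------------------

def gmdgm_elbo(params: GMDGMParams, post: PosteriorFactors, x,
               labels=None, cfg: LossConfig | None = None,
               anneal_w: float = 1.0, seed: int = 0,
               z: Tensor | None = None, n_draws: int | None = None) -> ObjectiveTerms:
    """Semi-supervised bound of the static mixture model.

    Per frame: sum_k r_k [log N(x; g(z_k), R) - KL(q(z|x,k) || p(z|y=k))]
    - KL(r || pi), plus the classification term on labeled frames.  With
    one-hot r the categorical KL is -log pi_y and the entropy vanishes;
    with classifier rows it contributes the +H(q(y|x)) of the unlabeled
    decomposition.
    """
    cfg = cfg or LossConfig(alpha=0.0)
    x = _as_batched_x(x)
    B, T, _ = x.shape
    K = params.K
    if labels is None:
        labels_arr = np.full((B, T), -1, dtype=np.int64)
    else:
        if isinstance(labels, LabelSequence):
            labels = labels.labels
        labels_arr = np.atleast_2d(np.asarray(labels, dtype=np.int64))
    labeled = (labels_arr >= 0).astype(np.float64)[..., None]
    onehot = _one_hot(labels_arr, K)
    r = post.class_probs * (1.0 - labeled) + Tensor(onehot * labeled)

    if z is None:
        z = post.sample_z(np.random.default_rng(seed), n_draws=n_draws)
    mean = params.emission_mean_t(z)                       # (..., B, T, K, Dx)
    logp_x = _diag_logpdf_t(x[:, :, None, :], mean, params.emission_logcov)
    recon = (r * logp_x).sum(axis=(-3, -2, -1))

    kl_z = _kl_diag_t(post.z_mean, post.z_logvar,
                      params.cluster_mean, params.cluster_logvar)  # (B, T, K)
    kl_z = (r * kl_z).sum()

    log_pi = log_softmax(params.pi0_logits, axis=-1)
    kl_y = (_xlogx(r) - r * log_pi).sum()

    weights = (np.ones(K) if cfg.class_weights is None
               else np.asarray(cfg.class_weights, float))
    w_frame = (onehot * weights).sum(axis=-1) * labeled[..., 0]
    classification = ((post.log_class_probs * Tensor(onehot * labeled)
                       ).sum(axis=-1) * w_frame).sum()
    return ObjectiveTerms(recon, kl_z, Tensor(0.0), kl_y, Tensor(0.0),
                          classification=classification, alpha=cfg.alpha,
                          anneal_w=anneal_w)
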