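"""Exact marginal likelihood for small non-recurrent switching models.

For a switching model whose discrete transitions do not depend on the
continuous latent (recurrence weights all zero), the marginal likelihood
factorizes over discrete state sequences:

    p(x_1:T) = sum_{y_1:T} p(y_1:T) p(x_1:T | y_1:T),

where each conditional term is a time-varying linear-Gaussian state-space
model evaluated exactly by the Kalman filter.  Enumerating all K^T state
sequences therefore gives the exact log marginal, which serves as the
independent ground truth that the variational lower bounds must not
exceed.  Recurrent transitions are rejected: they make the prior over
y_1:T depend on the z-path and the decomposition above invalid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax as np_log_softmax
from scipy.special import logsumexp as np_logsumexp
from scipy.stats import multivariate_normal

from .generative import RSLDSParams

_MAX_SEQUENCES = 10 ** 6


@dataclass
class EnumerationResult:
    log_marginal: float
    log_weights: np.ndarray          # per state-sequence, length K**T
    best_sequence: tuple              # argmax state sequence


def kalman_loglik(As, bs, Qs, C, d, S, x, mu0=None, V0=None) -> float:
    """Exact log p(x_1:T) for a (time-varying) linear-Gaussian model.

    z_1 ~ N(mu0, V0) (default N(0, I)); z_t = A_t z_{t-1} + b_t + N(0, Q_t)
    for t >= 2; x_t = C z_t + d + N(0, S).  As/bs/Qs are indexed by t-2
    (length T-1).  Covariances may be passed as diagonal vectors.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    T, Dx = x.shape
    C = np.atleast_2d(C)
    Dz = C.shape[1]
    S = np.diag(S) if np.ndim(S) == 1 else np.asarray(S)
    m = np.zeros(Dz) if mu0 is None else np.asarray(mu0, float)
    P = np.eye(Dz) if V0 is None else np.asarray(V0, float)
    ll = 0.0
    for t in range(T):
        if t > 0:
            A = np.atleast_2d(As[t - 1])
            Q = Qs[t - 1]
            Q = np.diag(Q) if np.ndim(Q) == 1 else np.asarray(Q)
            m = A @ m + bs[t - 1]
            P = A @ P @ A.T + Q
        innov_cov = C @ P @ C.T + S
        ll += multivariate_normal.logpdf(x[t], mean=C @ m + d, cov=innov_cov)
        gain = P @ C.T @ np.linalg.inv(innov_cov)
        m = m + gain @ (x[t] - (C @ m + d))
        P = P - gain @ C @ P
        P = 0.5 * (P + P.T)
    return float(ll)


def _check_oracle_valid(params: RSLDSParams) -> None:
    if params.is_recurrent:
        raise ValueError("oracle requires a non-recurrent model (rec_R = 0)")
    if not params.has_linear_emission:
        raise ValueError("oracle requires a linear emission")


def conditional_loglik(params: RSLDSParams, y_seq, x) -> float:
    """log p(x_1:T | y_1:T) via the Kalman filter."""
    _check_oracle_valid(params)
    y_seq = list(y_seq)
    As = [params.dyn_A.data[k] for k in y_seq[1:]]
    bs = [params.dyn_b.data[k] for k in y_seq[1:]]
    Qs = [params.dyn_Q[k] for k in y_seq[1:]]
    return kalman_loglik(As, bs, Qs, params.emission.C.data,
                         params.emission.d.data, params.emission_S, x)


def state_sequence_log_prior(params: RSLDSParams, y_seq) -> float:
    """log p(y_1:T) under pi and the z-free transition matrix softmax(r)."""
    _check_oracle_valid(params)
    log_pi = np.log(params.pi0)
    log_trans = np_log_softmax(params.rec_r.data, axis=-1)  # (K_prev, K)
    y_seq = list(y_seq)
    lp = log_pi[y_seq[0]]
    for prev, cur in zip(y_seq[:-1], y_seq[1:]):
        lp += log_trans[prev, cur]
    return float(lp)


def exact_log_marginal(params: RSLDSParams, x) -> EnumerationResult:
    """Enumerate all K^T discrete sequences and combine with Kalman terms."""
    _check_oracle_valid(params)
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    T = x.shape[0]
    K = params.K
    if K ** T > _MAX_SEQUENCES:
        raise ValueError(f"K^T = {K ** T} exceeds enumeration budget")
    log_weights = np.empty(K ** T)
    best, best_lw = None, -np.inf
    for i, y_seq in enumerate(itertools.product(range(K), repeat=T)):
        lw = state_sequence_log_prior(params, y_seq) + conditional_loglik(params, y_seq, x)
        log_weights[i] = lw
        if lw > best_lw:
            best, best_lw = y_seq, lw
    return EnumerationResult(float(np_logsumexp(log_weights)), log_weights, best)
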