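"""Generative models: recurrent switching (non)linear dynamical systems and
the static Gaussian-mixture deep generative model (GMDGM).

The switching model draws, per frame, a discrete behavior state y_t, a
continuous latent z_t, and an observation x_t:

    y_1 ~ Cat(pi),   z_1 ~ N(0, I)
    y_t | y_{t-1}, z_{t-1} ~ Cat(softmax(R_{y_{t-1}} z_{t-1} + r_{y_{t-1}}))
    z_t | z_{t-1}, y_t     ~ N(A_{y_t} z_{t-1} + b_{y_t}, Q_{y_t})
    x_t | z_t              ~ N(g(z_t), S)

with g either a shared linear map C z + d or a shared one-hidden-layer
dense network (hidden width = Dz).  Setting the recurrence weights
R_k = 0 recovers the plain SLDS with z-free Markov transitions; replacing
the linear dynamics/recurrence with one-hidden-layer networks gives the
nonlinear variant.  Covariances Q_k and S are diagonal.

The static GMDGM drops all temporal coupling:

    y ~ Cat(pi),  z | y ~ N(f(y), diag sigma^2(y)),  x | z ~ N(g(z), R).

Its per-class emission covariance is stored as ``emission_logcov`` (the
name ``R`` is reserved for the recurrence weights of the switching model).

Ancestral samplers double as the package's synthetic-data generators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as np_softmax

from .autodiff import Tensor
from .nn import MLP, Module, Parameter

_LOG2PI = float(np.log(2.0 * np.pi))


def diag_gauss_logpdf_np(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Log density of N(mean, diag var), summed over the last axis."""
    return -0.5 * np.sum(_LOG2PI + np.log(var) + (x - mean) ** 2 / var, axis=-1)


@dataclass
class SampledTrajectory:
    y: np.ndarray  # (T,) int states
    z: np.ndarray  # (T, Dz)
    x: np.ndarray  # (T, Dx)
    seed: int = 0

    def __post_init__(self):
        if not (len(self.y) == len(self.z) == len(self.x)):
            raise ValueError("inconsistent trajectory lengths")


class _LinearEmission(Module):
    def __init__(self, C: np.ndarray, d: np.ndarray):
        self.C = Parameter(np.asarray(C, dtype=np.float64))
        self.d = Parameter(np.asarray(d, dtype=np.float64))

    def mean_t(self, z: Tensor) -> Tensor:
        return z @ self.C.swapaxes(0, 1) + self.d

    def mean_np(self, z: np.ndarray) -> np.ndarray:
        return z @ self.C.data.T + self.d.data


class _MLPEmission(Module):
    def __init__(self, Dz: int, Dx: int, rng: np.random.Generator):
        self.net = MLP(Dz, Dz, Dx, rng, dtype=np.float64)

    def mean_t(self, z: Tensor) -> Tensor:
        return self.net(z)

    def mean_np(self, z: np.ndarray) -> np.ndarray:
        return self.net.forward_np(z)


class RSLDSParams(Module):
    """All generative parameters of the switching model.

    Learnable arrays are autodiff Parameters; NumPy views are exposed
    through properties for sampling and exact-inference code.
    """

    def __init__(self, pi0_logits, dyn_A=None, dyn_b=None, dyn_logQ=None,
                 rec_R=None, rec_r=None, emission=None, emission_logS=None,
                 dynamics_kind: str = "linear", recurrence_kind: str = "linear",
                 dyn_nets=None, rec_nets=None):
        self.pi0_logits = Parameter(np.asarray(pi0_logits, dtype=np.float64))
        self.K = len(self.pi0_logits.data)
        self.dynamics_kind = dynamics_kind
        self.recurrence_kind = recurrence_kind
        self.dyn_logQ = Parameter(np.asarray(dyn_logQ, dtype=np.float64))
        self.Dz = self.dyn_logQ.data.shape[1]
        if dynamics_kind == "linear":
            self.dyn_A = Parameter(np.asarray(dyn_A, dtype=np.float64))
            self.dyn_b = Parameter(np.asarray(dyn_b, dtype=np.float64))
            self.dyn_nets = None
        elif dynamics_kind == "mlp":
            self.dyn_nets = list(dyn_nets)
        else:
            raise ValueError(f"unknown dynamics_kind {dynamics_kind!r}")
        if recurrence_kind == "linear":
            self.rec_R = Parameter(np.asarray(rec_R, dtype=np.float64))
            self.rec_r = Parameter(np.asarray(rec_r, dtype=np.float64))
            self.rec_nets = None
        elif recurrence_kind == "mlp":
            self.rec_nets = list(rec_nets)
        else:
            raise ValueError(f"unknown recurrence_kind {recurrence_kind!r}")
        self.emission = emission
        self.emission_logS = Parameter(np.asarray(emission_logS, dtype=np.float64))
        self.Dx = len(self.emission_logS.data)

    def parameters(self):
        params = [self.pi0_logits, self.dyn_logQ, self.emission_logS]
        if self.dynamics_kind == "linear":
            params += [self.dyn_A, self.dyn_b]
        else:
            for net in self.dyn_nets:
                params += net.parameters()
        if self.recurrence_kind == "linear":
            params += [self.rec_R, self.rec_r]
        else:
            for net in self.rec_nets:
                params += net.parameters()
        params += self.emission.parameters()
        return params

    # -- NumPy views --------------------------------------------------------
    @property
    def pi0(self) -> np.ndarray:
        return np_softmax(self.pi0_logits.data)

    @property
    def dyn_Q(self) -> np.ndarray:
        return np.exp(self.dyn_logQ.data)

    @property
    def emission_S(self) -> np.ndarray:
        return np.exp(self.emission_logS.data)

    def dynamics_mean_np(self, k: int, z: np.ndarray) -> np.ndarray:
        if self.dynamics_kind == "linear":
            return z @ self.dyn_A.data[k].T + self.dyn_b.data[k]
        return self.dyn_nets[k].forward_np(z)

    def transition_logits_np(self, k_prev: int, z: np.ndarray) -> np.ndarray:
        if self.recurrence_kind == "linear":
            return z @ self.rec_R.data[k_prev].T + self.rec_r.data[k_prev]
        return self.rec_nets[k_prev].forward_np(z)

    def emission_mean_np(self, z: np.ndarray) -> np.ndarray:
        return self.emission.mean_np(z)

    # -- autodiff views (used by the variational objectives) ----------------
    def dynamics_mean_t(self, k: int, z: Tensor) -> Tensor:
        if self.dynamics_kind == "linear":
            return z @ self.dyn_A[k].swapaxes(0, 1) + self.dyn_b[k]
        return self.dyn_nets[k](z)

    def transition_logits_t(self, k_prev: int, z: Tensor) -> Tensor:
        if self.recurrence_kind == "linear":
            return z @ self.rec_R[k_prev].swapaxes(0, 1) + self.rec_r[k_prev]
        return self.rec_nets[k_prev](z)

    def emission_mean_t(self, z: Tensor) -> Tensor:
        return self.emission.mean_t(z)

    @property
    def is_recurrent(self) -> bool:
        return self.recurrence_kind != "linear" or bool(
            np.any(self.rec_R.data != 0.0))

    @property
    def has_linear_emission(self) -> bool:
        return isinstance(self.emission, _LinearEmission)


def make_rslds(K: int, Dz: int, Dx: int, seed: int = 0,
               dynamics_kind: str = "linear", recurrence_kind: str = "linear",
               emission_kind: str = "linear",
               emission_C: np.ndarray | None = None) -> RSLDSParams:
    """Random initialization of a switching model (used as a training start).

    Linear case: A_k = 0.99 I, b_k ~ N(0, 0.01), Q_k = 0.1 I, R = 0, r = 0,
    with the emission map supplied (e.g. PCA loadings) or random.
    """
    rng = np.random.default_rng(seed)
    pi0_logits = np.zeros(K)
    dyn_logQ = np.full((K, Dz), np.log(0.1))
    kwargs = dict(dynamics_kind=dynamics_kind, recurrence_kind=recurrence_kind)
    if dynamics_kind == "linear":
        kwargs["dyn_A"] = np.tile(0.99 * np.eye(Dz), (K, 1, 1))
        kwargs["dyn_b"] = rng.normal(0.0, 0.1, size=(K, Dz))
    else:
        kwargs["dyn_nets"] = [MLP(Dz, Dz, Dz, rng, dtype=np.float64) for _ in range(K)]
    if recurrence_kind == "linear":
        kwargs["rec_R"] = np.zeros((K, K, Dz))
        kwargs["rec_r"] = np.zeros((K, K))
    else:
        kwargs["rec_nets"] = [MLP(Dz, Dz, K, rng, dtype=np.float64) for _ in range(K)]
    if emission_kind == "linear":
        C = emission_C if emission_C is not None else rng.normal(0, 1, size=(Dx, Dz))
        emission = _LinearEmission(C, np.zeros(Dx))
    else:
        emission = _MLPEmission(Dz, Dx, rng)
    return RSLDSParams(pi0_logits, emission=emission,
                       emission_logS=np.full(Dx, np.log(0.5)),
                       dyn_logQ=dyn_logQ, **kwargs)


# -- operations --------------------------------------------------------------

def transition_distribution(params: RSLDSParams, y_prev: int,
                            z_prev: np.ndarray) -> np.ndarray:
    """p(y_t | y_{t-1}=y_prev, z_{t-1}=z_prev) as a length-K simplex."""
    if not (0 <= y_prev < params.K):
        raise ValueError("invalid state index")
    return np_softmax(params.transition_logits_np(y_prev, np.asarray(z_prev, float)))


def sample_rslds(params: RSLDSParams, T: int, seed: int = 0) -> SampledTrajectory:
    """Ancestral sampling y_1 -> z_1 -> x_1 -> y_2 -> ..."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    K, Dz, Dx = params.K, params.Dz, params.Dx
    y = np.empty(T, dtype=np.int64)
    z = np.empty((T, Dz))
    x = np.empty((T, Dx))
    Q_sd = np.sqrt(params.dyn_Q)
    S_sd = np.sqrt(params.emission_S)
    y[0] = rng.choice(K, p=params.pi0)
    z[0] = rng.standard_normal(Dz)
    x[0] = params.emission_mean_np(z[0]) + S_sd * rng.standard_normal(Dx)
    for t in range(1, T):
        probs = transition_distribution(params, int(y[t - 1]), z[t - 1])
        y[t] = rng.choice(K, p=probs)
        mean = params.dynamics_mean_np(int(y[t]), z[t - 1])
        z[t] = mean + Q_sd[y[t]] * rng.standard_normal(Dz)
        x[t] = params.emission_mean_np(z[t]) + S_sd * rng.standard_normal(Dx)
    return SampledTrajectory(y, z, x, seed=seed)


def log_joint(params: RSLDSParams, traj: SampledTrajectory) -> float:
    """Log joint density log p(x, y, z) of a full trajectory."""
    y, z, x = traj.y, traj.z, traj.x
    Q, S = params.dyn_Q, params.emission_S
    total = float(np.log(params.pi0[y[0]]))
    total += float(diag_gauss_logpdf_np(z[0], np.zeros(params.Dz), np.ones(params.Dz)))
    total += float(np.sum(diag_gauss_logpdf_np(x, params.emission_mean_np(z), S)))
    for t in range(1, len(y)):
        probs = transition_distribution(params, int(y[t - 1]), z[t - 1])
        total += float(np.log(probs[y[t]]))
        mean = params.dynamics_mean_np(int(y[t]), z[t - 1])
        total += float(diag_gauss_logpdf_np(z[t], mean, Q[y[t]]))
    return total


# -- GMDGM -------------------------------------------------------------------

class GMDGMParams(Module):
    """Static Gaussian-mixture deep generative model parameters."""

    def __init__(self, pi0_logits, cluster_mean, cluster_logvar, emission,
                 emission_logcov):
        self.pi0_logits = Parameter(np.asarray(pi0_logits, dtype=np.float64))
        self.cluster_mean = Parameter(np.asarray(cluster_mean, dtype=np.float64))
        self.cluster_logvar = Parameter(np.asarray(cluster_logvar, dtype=np.float64))
        self.emission = emission
        self.emission_logcov = Parameter(np.asarray(emission_logcov, dtype=np.float64))
        self.K = len(self.pi0_logits.data)
        self.Dz = self.cluster_mean.data.shape[1]
        self.Dx = len(self.emission_logcov.data)

    def parameters(self):
        return ([self.pi0_logits, self.cluster_mean, self.cluster_logvar,
                 self.emission_logcov] + self.emission.parameters())

    @property
    def pi0(self) -> np.ndarray:
        return np_softmax(self.pi0_logits.data)

    @property
    def cluster_var(self) -> np.ndarray:
        return np.exp(self.cluster_logvar.data)

    @property
    def emission_cov(self) -> np.ndarray:
        return np.exp(self.emission_logcov.data)

    def emission_mean_np(self, z: np.ndarray) -> np.ndarray:
        return self.emission.mean_np(z)

    def emission_mean_t(self, z: Tensor) -> Tensor:
        return self.emission.mean_t(z)


def make_gmdgm(K: int, Dz: int, Dx: int, seed: int = 0,
               emission_kind: str = "linear",
               cluster_mean: np.ndarray | None = None,
               emission_C: np.ndarray | None = None) -> GMDGMParams:
    rng = np.random.default_rng(seed)
    mean = cluster_mean if cluster_mean is not None else rng.normal(0, 1, (K, Dz))
    if emission_kind == "linear":
        C = emission_C if emission_C is not None else rng.normal(0, 1, (Dx, Dz))
        emission = _LinearEmission(C, np.zeros(Dx))
    else:
        emission = _MLPEmission(Dz, Dx, rng)
    return GMDGMParams(np.zeros(K), mean, np.full((K, Dz), np.log(0.3)),
                       emission, np.full(Dx, np.log(0.5)))


def sample_gmdgm(params: GMDGMParams, N: int, seed: int = 0) -> SampledTrajectory:
    """I.i.d. draws (no temporal coupling): y ~ Cat(pi), z | y, x | z."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    y = rng.choice(params.K, size=N, p=params.pi0)
    z = (params.cluster_mean.data[y]
         + np.sqrt(params.cluster_var[y]) * rng.standard_normal((N, params.Dz)))
    x = (params.emission_mean_np(z)
         + np.sqrt(params.emission_cov) * rng.standard_normal((N, params.Dx)))
    return SampledTrajectory(y, z, x, seed=seed)


def gmdgm_log_joint(params: GMDGMParams, y: np.ndarray, z: np.ndarray,
                    x: np.ndarray) -> np.ndarray:
    """Vectorized log p(x, y, z) for the static model."""
    y = np.asarray(y)
    lp = np.log(params.pi0)[y]
    lp = lp + diag_gauss_logpdf_np(z, params.cluster_mean.data[y],
                                   params.cluster_var[y])
    lp = lp + diag_gauss_logpdf_np(x, params.emission_mean_np(z),
                                   params.emission_cov)
    return lp


# -- presets -----------------------------------------------------------------

def well_separated_preset(self_prob: float = 0.98, seed: int = 12345) -> RSLDSParams:
    """Two-state switching model with well-separated state geometry.

    State fixed points sit at z* = +-(1, 1) (A = 0.9 I, b = +-0.1 (1,1)),
    latent noise Q = 0.02 I, a fixed 4x2 linear emission with observation
    noise S = 0.05 I, and sticky z-free transitions with self-probability
    `self_prob` (expected dwell ~ 1/(1-self_prob) frames).  Ground-truth
    states are recoverable from the observations, which makes this the
    reference condition for end-to-end recovery tests.
    """
    K, Dz, Dx = 2, 2, 4
    rng = np.random.default_rng(seed)
    A = np.tile(0.9 * np.eye(Dz), (K, 1, 1))
    b = np.stack([0.1 * np.ones(Dz), -0.1 * np.ones(Dz)])
    logQ = np.full((K, Dz), np.log(0.02))
    self_logit = np.log(self_prob / (1 - self_prob))
    rec_r = np.stack([np.eye(K)[k] * self_logit for k in range(K)])
    C = rng.normal(0, 1, size=(Dx, Dz)) * 0.8
    emission = _LinearEmission(C, np.zeros(Dx))
    return RSLDSParams(np.zeros(K), dyn_A=A, dyn_b=b, dyn_logQ=logQ,
                       rec_R=np.zeros((K, K, Dz)), rec_r=rec_r,
                       emission=emission, emission_logS=np.full(Dx, np.log(0.05)))


def random_tiny_slds(K: int, Dz: int, Dx: int, seed: int,
                     recurrent: bool = False) -> RSLDSParams:
    """Small random stable instance for oracle and bound-property tests."""
    rng = np.random.default_rng(seed)
    A = rng.normal(0, 0.5, size=(K, Dz, Dz))
    for k in range(K):
        radius = max(np.abs(np.linalg.eigvals(A[k])))
        if radius > 0.9:
            A[k] *= 0.9 / radius
    b = rng.normal(0, 0.5, size=(K, Dz))
    logQ = np.log(rng.uniform(0.3, 1.0, size=(K, Dz)))
    rec_R = rng.normal(0, 0.5, size=(K, K, Dz)) if recurrent else np.zeros((K, K, Dz))
    rec_r = rng.normal(0, 0.5, size=(K, K))
    C = rng.normal(0, 1, size=(Dx, Dz))
    d = rng.normal(0, 0.5, size=Dx)
    logS = np.log(rng.uniform(0.3, 1.0, size=Dx))
    pi_logits = rng.normal(0, 0.5, size=K)
    return RSLDSParams(pi_logits, dyn_A=A, dyn_b=b, dyn_logQ=logQ,
                       rec_R=rec_R, rec_r=rec_r,
                       emission=_LinearEmission(C, d), emission_logS=logS)
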