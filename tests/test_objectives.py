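"""Variational objectives: closed-form KLs, labeled/unlabeled bounds, the
one-hot reduction identity, mixed-loss reductions, and the static-model
bound decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import rel_entr

from ethoseg.autodiff import Tensor
from ethoseg.features import LabelSequence
from ethoseg.generative import (diag_gauss_logpdf_np, make_gmdgm,
                                gmdgm_log_joint, random_tiny_slds)
from ethoseg.objectives import (LossConfig, categorical_kl, gaussian_kl_diag,
                                gmdgm_elbo, labeled_elbo, semisupervised_loss,
                                unlabeled_elbo)
from ethoseg.posteriors import PosteriorFactors

TERMS = ("recon", "kl_z_init", "kl_z_dyn", "kl_y_init", "kl_y_trans")


def random_posterior(rng, T, K, Dz, one_hot=False):
    if one_hot:
        labels = rng.integers(0, K, size=T)
        cp = np.eye(K)[labels][None]
    else:
        labels = None
        cp = rng.dirichlet(np.ones(K), size=(1, T))
    return labels, PosteriorFactors.from_arrays(
        cp, rng.normal(size=(1, T, K, Dz)),
        np.log(rng.uniform(0.2, 1.0, size=(1, T, K, Dz))))


class TestClosedFormKL:
    def test_gaussian_kl_examples(self):
        assert gaussian_kl_diag([0.0], [1.0], [0.0], [1.0]) == 0.0
        assert np.isclose(gaussian_kl_diag([1.0], [1.0], [0.0], [1.0]), 0.5)
        expected = 0.5 * (4 - 1 - np.log(4))  # ~0.80685
        assert np.isclose(gaussian_kl_diag([0.0], [4.0], [0.0], [1.0]),
                          expected, atol=1e-9)

    def test_gaussian_kl_rejects_non_positive_variance(self):
        with pytest.raises(ValueError):
            gaussian_kl_diag([0.0], [0.0], [0.0], [1.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_gaussian_kl_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        kl = gaussian_kl_diag(rng.normal(size=3), rng.uniform(0.1, 3, 3),
                              rng.normal(size=3), rng.uniform(0.1, 3, 3))
        assert kl >= -1e-12

    def test_categorical_kl_examples(self):
        assert categorical_kl([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert np.isclose(categorical_kl([1.0, 0.0], [0.5, 0.5]), np.log(2))
        q = np.full(4, 0.25)
        p = np.array([0.7, 0.1, 0.1, 0.1])
        assert np.isclose(categorical_kl(q, p), rel_entr(q, p).sum(), atol=1e-12)

    def test_categorical_kl_support_mismatch_is_infinite(self):
        assert categorical_kl([0.5, 0.5], [1.0, 0.0]) == np.inf

    def test_categorical_kl_rejects_non_simplex(self):
        with pytest.raises(ValueError):
            categorical_kl([0.7, 0.7], [0.5, 0.5])


class TestOneHotReduction:
    @pytest.mark.parametrize("seed", range(6))
    def test_every_unlabeled_term_reduces_to_labeled_term(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 4))
        T = int(rng.integers(2, 6))
        Dz = int(rng.integers(1, 3))
        Dx = int(rng.integers(1, 3))
        params = random_tiny_slds(K, Dz, Dx, seed=seed + 100, recurrent=True)
        labels, post = random_posterior(rng, T, K, Dz, one_hot=True)
        x = rng.normal(size=(T, Dx))
        t_lab = labeled_elbo(params, post, x, labels, seed=seed)
        t_unl = unlabeled_elbo(params, post, x, seed=seed)
        for name in TERMS:
            a = float(getattr(t_lab, name).data)
            b = float(getattr(t_unl, name).data)
            assert abs(a - b) < 1e-6, name

    def test_labeled_elbo_rejects_unlabeled_frames(self):
        params = random_tiny_slds(2, 1, 1, seed=0)
        rng = np.random.default_rng(0)
        _, post = random_posterior(rng, 3, 2, 1)
        with pytest.raises(ValueError):
            labeled_elbo(params, post, rng.normal(size=(3, 1)),
                         np.array([0, -1, 1]))


def test_single_frame_single_state_matches_hand_coded_vae_bound():
    """T=1, K=1: bound = log N(x; C z~ + d, S) + log pi - KL(q || N(0, I))."""
    Dz, Dx, seed = 2, 3, 13
    params = random_tiny_slds(K=1, Dz=Dz, Dx=Dx, seed=1)
    rng = np.random.default_rng(5)
    mu = rng.normal(size=(1, 1, 1, Dz))
    logvar = np.log(rng.uniform(0.3, 1.0, size=(1, 1, 1, Dz)))
    post = PosteriorFactors.from_arrays(np.ones((1, 1, 1)), mu, logvar)
    x = rng.normal(size=(1, Dx))
    terms = labeled_elbo(params, post, x, np.array([0]), seed=seed)
    # independent single-frame computation
    eps = np.random.default_rng(seed).standard_normal((1, 1, 1, Dz))
    z = mu + np.exp(0.5 * logvar) * eps
    recon = diag_gauss_logpdf_np(
        x[0], params.emission.C.data @ z[0, 0, 0] + params.emission.d.data,
        params.emission_S)
    kl = gaussian_kl_diag(mu.ravel(), np.exp(logvar).ravel(),
                          np.zeros(Dz), np.ones(Dz))
    expected = float(recon) - kl + 0.0  # log pi = 0 for K=1
    assert np.isclose(float(terms.elbo.data), expected, atol=1e-9)


def test_unlabeled_bound_invariant_to_permuting_identical_states():
    K, Dz, Dx, T = 3, 2, 2, 5
    params = random_tiny_slds(K, Dz, Dx, seed=2)
    # make all states identical and transitions symmetric
    for arr in (params.dyn_A, params.dyn_b, params.dyn_logQ):
        arr.data[:] = arr.data[:1]
    params.rec_R.data[:] = 0.0
    params.rec_r.data[:] = 0.0
    params.pi0_logits.data[:] = 0.0
    rng = np.random.default_rng(3)
    cp = rng.dirichlet(np.ones(K), size=(1, T))
    mu = np.repeat(rng.normal(size=(1, T, 1, Dz)), K, axis=2)
    logvar = np.repeat(np.log(rng.uniform(0.3, 1, size=(1, T, 1, Dz))), K, axis=2)
    z = Tensor(np.repeat(rng.normal(size=(1, T, 1, Dz)), K, axis=2))
    x = rng.normal(size=(T, Dx))
    post = PosteriorFactors.from_arrays(cp, mu, logvar)
    base = float(unlabeled_elbo(params, post, x, z=z).elbo.data)
    perm = np.array([2, 0, 1])
    post_p = PosteriorFactors.from_arrays(cp[:, :, perm], mu, logvar)
    permuted = float(unlabeled_elbo(params, post_p, x, z=z).elbo.data)
    assert np.isclose(base, permuted, atol=1e-9)


class TestSemisupervisedLoss:
    def setup_method(self):
        self.rng = np.random.default_rng(7)
        self.K, self.T, self.Dz, self.Dx = 2, 6, 2, 2
        self.params = random_tiny_slds(self.K, self.Dz, self.Dx, seed=4,
                                       recurrent=True)
        _, self.post = random_posterior(self.rng, self.T, self.K, self.Dz)
        self.x = self.rng.normal(size=(self.T, self.Dx))

    def test_fully_labeled_reduces_to_labeled_elbo_plus_classification(self):
        labels = self.rng.integers(0, self.K, size=self.T)
        weights = np.array([0.8, 1.2])
        cfg = LossConfig(alpha=3.0, class_weights=weights)
        # one-hot substitution changes the posterior weights, so compare
        # against labeled_elbo evaluated with identical samples
        onehot_post = PosteriorFactors.from_arrays(
            np.eye(self.K)[labels][None], self.post.z_mean.data,
            self.post.z_logvar.data)
        t_ss = semisupervised_loss(self.params, self.post, self.x,
                                   labels, cfg, anneal_w=1.0, seed=9)
        t_lab = labeled_elbo(self.params, onehot_post, self.x, labels, seed=9)
        ll = float((np.log(np.maximum(
            self.post.class_probs.data[0, np.arange(self.T), labels], 1e-300))
            * weights[labels]).sum())
        assert np.isclose(float(t_ss.total.data),
                          float(t_lab.elbo.data) + 3.0 * ll, atol=1e-8)

    def test_fully_unlabeled_reduces_to_unlabeled_elbo(self):
        labels = np.full(self.T, -1)
        cfg = LossConfig(alpha=100.0)
        t_ss = semisupervised_loss(self.params, self.post, self.x, labels,
                                   cfg, anneal_w=1.0, seed=11)
        t_unl = unlabeled_elbo(self.params, self.post, self.x, seed=11)
        assert float(t_ss.classification.data) == 0.0
        assert np.isclose(float(t_ss.total.data), float(t_unl.elbo.data),
                          atol=1e-9)

    def test_background_frames_never_enter_classification(self):
        labels = np.array([0, -2, -2, 1, -1, 0])
        cfg = LossConfig(alpha=5.0)
        t = semisupervised_loss(self.params, self.post, self.x, labels, cfg,
                                anneal_w=1.0, seed=0)
        labels_no_bg = np.where(labels == -2, -1, labels)
        t2 = semisupervised_loss(self.params, self.post, self.x, labels_no_bg,
                                 cfg, anneal_w=1.0, seed=0)
        assert np.isclose(float(t.classification.data),
                          float(t2.classification.data), atol=1e-12)

    def test_kl_terms_non_negative_and_total_finite(self):
        labels = np.array([0, 1, -1, -1, 1, 0])
        t = semisupervised_loss(self.params, self.post, self.x, labels,
                                LossConfig(), anneal_w=0.7, seed=1)
        for name in ("kl_z_init", "kl_z_dyn", "kl_y_init", "kl_y_trans"):
            assert float(getattr(t, name).data) >= -1e-9, name
        assert np.isfinite(float(t.total.data))

    def test_total_reproduces_signed_combination(self):
        labels = np.array([0, 1, -1, -1, 1, 0])
        cfg = LossConfig(alpha=2.5)
        w = 0.3
        t = semisupervised_loss(self.params, self.post, self.x, labels, cfg,
                                anneal_w=w, seed=1)
        f = t.as_floats()
        expected = (f["recon"] - w * (f["kl_z_init"] + f["kl_z_dyn"]
                                      + f["kl_y_init"] + f["kl_y_trans"])
                    + 2.5 * f["classification"])
        assert np.isclose(f["total"], expected, atol=1e-9)

    def test_annealing_scales_only_kl_terms(self):
        labels = np.array([0, 1, -1, -1, 1, 0])
        cfg = LossConfig(alpha=0.0)
        t0 = semisupervised_loss(self.params, self.post, self.x, labels, cfg,
                                 anneal_w=0.0, seed=2)
        assert np.isclose(float(t0.total.data), float(t0.recon.data), atol=1e-9)


class TestGMDGMBound:
    def _setup(self, K=3, Dz=2, Dx=2, seed=0):
        rng = np.random.default_rng(seed)
        params = make_gmdgm(K, Dz, Dx, seed=seed)
        params.cluster_mean.data[:] = rng.normal(size=(K, Dz))
        _, post = random_posterior(rng, 1, K, Dz)
        x = rng.normal(size=(1, Dx))
        return rng, params, post, x

    def test_one_hot_weights_give_labeled_bound_exactly(self):
        rng, params, post, x = self._setup()
        z = Tensor(rng.normal(size=(1, 1, 3, 2)))
        t_u = gmdgm_elbo(params, post, x, labels=np.array([[1]]),
                         cfg=LossConfig(alpha=0.0), z=z)
        # hand-compute L_l(x, 1) with the same sample
        recon = diag_gauss_logpdf_np(
            x[0], params.emission_mean_np(z.data[0, 0, 1]), params.emission_cov)
        kl = gaussian_kl_diag(post.z_mean.data[0, 0, 1],
                              np.exp(post.z_logvar.data[0, 0, 1]),
                              params.cluster_mean.data[1],
                              params.cluster_var[1])
        expected = float(recon) + np.log(params.pi0[1]) - kl
        assert np.isclose(float(t_u.elbo.data), expected, atol=1e-9)

    def test_uniform_weights_over_identical_clusters_add_entropy(self):
        rng, params, post, x = self._setup(seed=3)
        K = 3
        params.cluster_mean.data[:] = params.cluster_mean.data[:1]
        params.cluster_logvar.data[:] = params.cluster_logvar.data[:1]
        params.pi0_logits.data[:] = 0.0
        mu = np.repeat(rng.normal(size=(1, 1, 1, 2)), K, axis=2)
        logvar = np.repeat(np.log(rng.uniform(0.3, 1, (1, 1, 1, 2))), K, axis=2)
        z = Tensor(np.repeat(rng.normal(size=(1, 1, 1, 2)), K, axis=2))
        post_u = PosteriorFactors.from_arrays(np.full((1, 1, K), 1 / K), mu, logvar)
        post_l = PosteriorFactors.from_arrays(np.eye(K)[[0]][None], mu, logvar)
        t_u = gmdgm_elbo(params, post_u, x, z=z)
        t_l = gmdgm_elbo(params, post_l, x, labels=np.array([[0]]),
                         cfg=LossConfig(alpha=0.0), z=z)
        assert np.isclose(float(t_u.elbo.data),
                          float(t_l.elbo.data) + np.log(K), atol=1e-9)

    def test_decomposed_bound_matches_monte_carlo_joint_expectation(self):
        """The decomposed unlabeled bound must equal the direct MC estimate
        of E_q[log p(x,y,z) - log q(y,z|x)] within 3 combined SEM."""
        rng, params, post, x = self._setup(seed=5)
        n = 10 ** 4
        t = gmdgm_elbo(params, post, x, n_draws=n)
        per_draw = t.elbo.data  # (n,)
        dec_mean = per_draw.mean()
        dec_sem = per_draw.std() / np.sqrt(n)
        # brute-force joint expectation
        q = post.class_probs.data[0, 0]
        mu = post.z_mean.data[0, 0]
        sd = np.exp(0.5 * post.z_logvar.data[0, 0])
        mc_rng = np.random.default_rng(99)
        ys = mc_rng.choice(len(q), size=n, p=q)
        zs = mu[ys] + sd[ys] * mc_rng.standard_normal((n, mu.shape[-1]))
        logp = gmdgm_log_joint(params, ys, zs, np.repeat(x, n, axis=0))
        logq = (np.log(q[ys])
                + diag_gauss_logpdf_np(zs, mu[ys], np.exp(post.z_logvar.data[0, 0])[ys]))
        vals = logp - logq
        mc_mean = vals.mean()
        mc_sem = vals.std() / np.sqrt(n)
        assert abs(dec_mean - mc_mean) <= 3 * np.hypot(dec_sem, mc_sem)
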