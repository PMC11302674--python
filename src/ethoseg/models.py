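"""Model / Results interface over the segmentation pipeline.

Each model is built from data (a list of sessions) plus configuration,
and ``fit()`` returns a results object carrying the trained parameters,
the per-epoch objective log, prediction and latent-embedding methods, a
``summary()`` table, and the evaluation metrics.

Three model families are exposed:

* :class:`SupervisedTCN` — frame classifier trained with weighted
  cross-entropy on labeled frames only.
* :class:`GaussianMixtureDGM` — the static semi-supervised mixture model;
  with ``temporal_posterior=True`` it becomes the hybrid that pairs the
  static generative model with the temporal-context TCN posteriors.
* :class:`SemiSupervisedSLDS` — the semi-supervised switching dynamical
  system; ``nonlinear=True`` replaces the linear latent dynamics and
  recurrence maps with one-hidden-layer dense networks.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import evaluation
from .features import (FeatureSequence, LabelSequence, Standardizer,
                       add_velocity, choose_latent_dim)
from .generative import make_gmdgm, make_rslds
from .objectives import LossConfig
from .posteriors import AmortizedPosterior, classify
from .tcn import TCNConfig
from .training import TrainConfig, class_weights, train


class _BaseSegmenter:
    """Shared session preparation: optional velocity concatenation and
    per-column z-scoring with training-split statistics."""

    model_kind = ""

    def __init__(self, sessions, class_names, use_velocity: bool = False,
                 standardize: bool = True, tcn_config: TCNConfig | None = None,
                 loss_config: LossConfig | None = None, seed: int = 0):
        if not sessions:
            raise ValueError("need at least one session")
        self.class_names = list(class_names)
        self.K = len(self.class_names)
        self.use_velocity = use_velocity
        self.standardize = standardize
        self.seed = seed
        self.tcn_config = tcn_config or TCNConfig()
        self.loss_config = loss_config or LossConfig()
        raw = [(add_velocity(fs) if use_velocity else fs, ls)
               for fs, ls in sessions]
        self.scaler = Standardizer()
        if standardize:
            self.scaler.fit([fs.values for fs, _ in raw])
        else:
            D = raw[0][0].n_features
            self.scaler.mean, self.scaler.std = np.zeros(D), np.ones(D)
        self.sessions = [(self.scaler.transform_sequence(fs), ls)
                         for fs, ls in raw]
        self.in_dim = self.sessions[0][0].n_features

    def _prepare(self, fs: FeatureSequence) -> FeatureSequence:
        if self.use_velocity:
            fs = add_velocity(fs)
        return self.scaler.transform_sequence(fs)

    def _all_labels(self) -> LabelSequence:
        stacked = np.concatenate([ls.labels for _, ls in self.sessions])
        return LabelSequence(stacked, self.class_names)

    def _resolve_class_weights(self):
        if self.loss_config.class_weights is None:
            self.loss_config.class_weights = class_weights(self._all_labels())

    def _fit(self, posterior, gen_params, train_config) -> "SegmentationResults":
        cfg = train_config or TrainConfig(model_kind=self.model_kind,
                                          seed=self.seed)
        cfg.model_kind = self.model_kind
        self._resolve_class_weights()
        state = train(self.sessions, cfg, posterior, gen_params,
                      self.loss_config)
        return SegmentationResults(self, posterior, gen_params, cfg, state)


class SupervisedTCN(_BaseSegmenter):
    """Fully supervised dilated-TCN frame classifier."""

    model_kind = "tcn_supervised"

    def __init__(self, sessions, class_names, n_latents: int | None = None,
                 **kwargs):
        super().__init__(sessions, class_names, **kwargs)
        self.Dz = n_latents or 1
        self.posterior = AmortizedPosterior(
            self.in_dim, self.K, self.Dz, self.tcn_config, temporal=True,
            rng=np.random.default_rng(self.seed))

    def fit(self, train_config: TrainConfig | None = None):
        return self._fit(self.posterior, None, train_config)


class GaussianMixtureDGM(_BaseSegmenter):
    """Static semi-supervised Gaussian-mixture deep generative model.

    `temporal_posterior=False` uses per-frame dense posteriors (fully
    static); True pairs the static generative model with the temporal
    TCN posteriors (the hybrid ablation).
    """

    def __init__(self, sessions, class_names, n_latents: int | None = None,
                 temporal_posterior: bool = False,
                 emission_kind: str = "linear", **kwargs):
        super().__init__(sessions, class_names, **kwargs)
        self.model_kind = "gmdgm_tcn" if temporal_posterior else "gmdgm"
        self.Dz = n_latents or self._choose_dim()
        self.gen_params = make_gmdgm(self.K, self.Dz, self.in_dim,
                                     seed=self.seed, emission_kind=emission_kind,
                                     emission_C=self._pca_loadings(self.Dz))
        self.posterior = AmortizedPosterior(
            self.in_dim, self.K, self.Dz, self.tcn_config,
            temporal=temporal_posterior, rng=np.random.default_rng(self.seed))

    def _choose_dim(self) -> int:
        stacked = np.vstack([fs.values for fs, _ in self.sessions])
        return choose_latent_dim(FeatureSequence(stacked))

    def _pca_loadings(self, Dz: int) -> np.ndarray:
        stacked = np.vstack([fs.values for fs, _ in self.sessions])
        pca = PCA(n_components=Dz).fit(stacked)
        return (pca.components_ * np.sqrt(pca.explained_variance_)[:, None]).T

    def fit(self, train_config: TrainConfig | None = None):
        return self._fit(self.posterior, self.gen_params, train_config)


class SemiSupervisedSLDS(_BaseSegmenter):
    """Semi-supervised switching (non)linear dynamical system.

    The continuous latent dimensionality defaults to the smallest number
    of principal components explaining 95% of feature variance; the
    emission map is initialized from the top-Dz PCA loadings.
    """

    def __init__(self, sessions, class_names, n_latents: int | None = None,
                 nonlinear: bool = False, emission_kind: str = "linear",
                 **kwargs):
        super().__init__(sessions, class_names, **kwargs)
        self.model_kind = "s3nlds" if nonlinear else "s3lds"
        self.Dz = n_latents or self._choose_dim()
        kind = "mlp" if nonlinear else "linear"
        self.gen_params = make_rslds(
            self.K, self.Dz, self.in_dim, seed=self.seed,
            dynamics_kind=kind, recurrence_kind=kind,
            emission_kind=emission_kind,
            emission_C=self._pca_loadings(self.Dz))
        self.posterior = AmortizedPosterior(
            self.in_dim, self.K, self.Dz, self.tcn_config, temporal=True,
            rng=np.random.default_rng(self.seed))

    _choose_dim = GaussianMixtureDGM._choose_dim
    _pca_loadings = GaussianMixtureDGM._pca_loadings

    def fit(self, train_config: TrainConfig | None = None):
        return self._fit(self.posterior, self.gen_params, train_config)


class SegmentationResults:
    """Fitted-model results: parameters, training log, predictions,
    latent embeddings, metrics, and a text summary."""

    def __init__(self, model: _BaseSegmenter, posterior, gen_params,
                 train_config: TrainConfig, state):
        self.model = model
        self.posterior = posterior
        self.gen_params = gen_params
        self.train_config = train_config
        self.state = state
        self.history = pd.DataFrame(state.history)
        self.val_history = pd.DataFrame(state.val_history)

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, fs: FeatureSequence) -> np.ndarray:
        """Per-frame class probabilities q(y_t | x_Tt) on a raw session."""
        return classify(self.posterior, self.model._prepare(fs))

    def predict_states(self, fs: FeatureSequence) -> np.ndarray:
        return np.argmax(self.predict_proba(fs), axis=-1)

    def latents(self, fs: FeatureSequence) -> np.ndarray:
        """Posterior latent means of the most probable class per frame."""
        prepared = self.model._prepare(fs)
        probs = classify(self.posterior, prepared)
        factors = self.posterior(prepared.values[None].astype(np.float32))
        mu = np.asarray(factors.z_mean.data[0])
        best = np.argmax(probs, axis=-1)
        return mu[np.arange(len(best)), best]

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, sessions) -> evaluation.EvalReport:
        """F1/confusion plus TP/FP entropy over one or more sessions."""
        preds, probs, labels = [], [], []
        for fs, ls in sessions:
            p = self.predict_proba(fs)
            probs.append(p)
            preds.append(np.argmax(p, axis=-1))
            labels.append(ls.labels)
        ls_all = LabelSequence(np.concatenate(labels), self.model.class_names)
        pred_all = np.concatenate(preds)
        report = evaluation.f1_report(pred_all, ls_all)
        tp, fp = evaluation.entropy_report(np.vstack(probs), pred_all, ls_all)
        report.tp_entropy, report.fp_entropy = tp, fp
        return report

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Action segmentation results",
            "=" * 45,
            f"model kind:        {self.model.model_kind}",
            f"classes (K):       {self.model.K}",
            f"input dim:         {self.model.in_dim}",
            f"latent dim (Dz):   {getattr(self.model, 'Dz', '-')}",
            f"parameters:        {self.posterior.n_parameters() + (self.gen_params.n_parameters() if self.gen_params else 0)}",
            f"epochs trained:    {self.state.epoch}",
            f"best val loss:     {self.state.best_val:.4f}" if np.isfinite(self.state.best_val) else "best val loss:     n/a",
            "-" * 45,
            "final epoch objective terms (per batch mean):",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            for key in ("recon", "kl_z_init", "kl_z_dyn", "kl_y_init",
                        "kl_y_trans", "classification", "total"):
                if key in last:
                    lines.append(f"  {key:<16} {last[key]: .4f}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], -self.history["total"], label="-total")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    def plot_ethogram(self, fs: FeatureSequence, labels=None, ax=None):
        import matplotlib.pyplot as plt
        probs = self.predict_proba(fs)
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2))
        ax.imshow(probs.T, aspect="auto", interpolation="nearest",
                  cmap="viridis")
        ax.set_xlabel("frame")
        ax.set_yticks(range(self.model.K))
        ax.set_yticklabels(self.model.class_names)
        if labels is not None:
            ax.plot(np.where(labels.labels >= 0, labels.labels, np.nan),
                    "r.", markersize=2)
        return ax

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: parameter arrays + embedded config."""
        arrays = {f"post_{i}": a for i, a in
                  enumerate(self.posterior.state_arrays())}
        if self.gen_params is not None:
            arrays.update({f"gen_{i}": a for i, a in
                           enumerate(self.gen_params.state_arrays())})
        tc = self.model.tcn_config
        meta = dict(
            model_kind=self.model.model_kind,
            class_names=self.model.class_names,
            in_dim=self.model.in_dim,
            Dz=int(getattr(self.model, "Dz", 1)),
            use_velocity=self.model.use_velocity,
            scaler_mean=self.model.scaler.mean.tolist(),
            scaler_std=self.model.scaler.std.tolist(),
            tcn=dict(n_blocks=tc.n_blocks,
                     n_sublayers_per_block=tc.n_sublayers_per_block,
                     temporal_lags=tc.temporal_lags, n_filters=tc.n_filters,
                     dropout_p=tc.dropout_p),
        )
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @staticmethod
    def load_checkpoint(path) -> dict:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            post = [data[k] for k in sorted(
                (k for k in data.files if k.startswith("post_")),
                key=lambda s: int(s.split("_")[1]))]
            gen = [data[k] for k in sorted(
                (k for k in data.files if k.startswith("gen_")),
                key=lambda s: int(s.split("_")[1]))]
        return {"meta": meta, "posterior_arrays": post, "gen_arrays": gen}
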