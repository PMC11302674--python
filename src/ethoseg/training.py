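"""Optimization loop shared by the supervised classifier, the static
mixture models, and the switching models.

Protocol: Adam (learning rate 1e-4 by default), batches of 8 contiguous
non-overlapping 1000-frame chunks, class weights inversely proportional
to labeled class frequency, and linear annealing of the KL / discrete
log-probability terms from 0 to 1 over the first 100 epochs.  The loss
minimized each step is the negative objective normalized per frame.  A
fraction of chunks is held out to select the best checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSequence, LabelSequence
from .nn import Adam
from .objectives import LossConfig, ObjectiveTerms, gmdgm_elbo, semisupervised_loss
from .posteriors import AmortizedPosterior

MODEL_KINDS = ("tcn_supervised", "gmdgm", "gmdgm_tcn", "s3lds", "s3nlds")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    n_epochs: int = 500
    batch_sequences: int = 8
    sequence_length: int = 1000
    anneal_epochs: int = 100
    seed: int = 0
    model_kind: str = "s3lds"
    val_fraction: float = 0.10
    val_every: int = 5

    def __post_init__(self):
        for name in ("learning_rate", "n_epochs", "batch_sequences",
                     "sequence_length", "anneal_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")


@dataclass
class TrainState:
    epoch: int = 0
    history: list = field(default_factory=list)   # one dict per epoch
    best_val: float = np.inf
    best_arrays: list | None = None
    val_history: list = field(default_factory=list)


def class_weights(labels: LabelSequence) -> np.ndarray:
    """w_k proportional to 1/frequency over labeled frames, normalized to
    mean 1.  Every class must appear in the labeled training frames."""
    y = labels.labels[labels.labeled_mask]
    K = labels.n_classes
    counts = np.bincount(y, minlength=K)
    if np.any(counts == 0):
        missing = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"class {missing} absent from labeled training frames")
    w = 1.0 / (counts / counts.sum())
    return w / w.mean()


def anneal_weight(epoch: int, cfg: TrainConfig) -> float:
    """Linear ramp 0 -> 1 over `anneal_epochs`, then constant 1."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return min(epoch / cfg.anneal_epochs, 1.0)


def make_chunks(sessions, sequence_length: int):
    """Cut sessions into contiguous non-overlapping chunks.

    Sessions shorter than `sequence_length` are kept whole; trailing
    remainders are kept as their own (shorter) chunk when at least 2
    frames long.  Returns (x_chunks float32, label_chunks int64).
    """
    xs, ys = [], []
    for fs, ls in sessions:
        values = fs.values.astype(np.float32)
        labels = ls.labels if ls is not None else np.full(len(values), -1, np.int64)
        T = len(values)
        for start in range(0, T, sequence_length):
            stop = min(start + sequence_length, T)
            if stop - start < 2:
                continue
            xs.append(values[start:stop])
            ys.append(labels[start:stop])
    return xs, ys


def _batches(indices, lengths, batch_size, rng):
    """Yield batches of chunk indices with equal chunk length."""
    by_len = {}
    for i in indices:
        by_len.setdefault(lengths[i], []).append(i)
    groups = []
    for length in sorted(by_len):
        idx = np.array(by_len[length])
        rng.shuffle(idx)
        for j in range(0, len(idx), batch_size):
            groups.append(idx[j:j + batch_size])
    order = rng.permutation(len(groups))
    for g in order:
        yield groups[g]


def _loss_terms(model_kind, posterior, gen_params, x, labels, loss_cfg,
                anneal_w, seed, train, rng) -> ObjectiveTerms:
    from .autodiff import Tensor  # local import to avoid cycle at module load
    factors = posterior(x, train=train, rng=rng)
    if model_kind == "tcn_supervised":
        K = posterior.K
        onehot = np.zeros(labels.shape + (K,))
        valid = labels >= 0
        onehot[(*np.nonzero(valid), labels[valid])] = 1.0
        weights = (np.ones(K) if loss_cfg.class_weights is None
                   else loss_cfg.class_weights)
        w_frame = (onehot * weights).sum(axis=-1)
        ce = ((factors.log_class_probs * Tensor(onehot)).sum(axis=-1)
              * w_frame).sum()
        zero = Tensor(0.0)
        return ObjectiveTerms(zero, zero, zero, zero, zero,
                              classification=ce, alpha=1.0, anneal_w=1.0)
    if model_kind in ("gmdgm", "gmdgm_tcn"):
        return gmdgm_elbo(gen_params, factors, x, labels, loss_cfg,
                          anneal_w=anneal_w, seed=seed)
    return semisupervised_loss(gen_params, factors, x, labels, loss_cfg,
                               anneal_w=anneal_w, seed=seed)


def train(sessions, cfg: TrainConfig, posterior: AmortizedPosterior,
          gen_params=None, loss_cfg: LossConfig | None = None) -> TrainState:
    """Minimize the negative per-frame objective by Adam.

    `sessions` is a list of (FeatureSequence, LabelSequence) pairs whose
    features are already engineered/standardized.  Returns a TrainState
    with a per-epoch log of every objective term; the parameters left in
    `posterior`/`gen_params` are the best-validation snapshot.
    """
    if not sessions:
        raise ValueError("need at least one session")
    loss_cfg = loss_cfg or LossConfig()
    xs, ys = make_chunks(sessions, cfg.sequence_length)
    n = len(xs)
    rng = np.random.default_rng(cfg.seed)
    dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
    order = rng.permutation(n)
    n_val = int(round(cfg.val_fraction * n)) if n > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    lengths = [len(x) for x in xs]

    modules = [posterior] + ([gen_params] if gen_params is not None else [])
    params = [p for m in modules for p in m.parameters()]
    opt = Adam(params, lr=cfg.learning_rate)
    state = TrainState()

    def snapshot():
        return [p.data.copy() for p in params]

    def evaluate_val(epoch_seed):
        totals, frames = 0.0, 0
        for i in val_idx:
            terms = _loss_terms(cfg.model_kind, posterior, gen_params,
                                xs[i][None], ys[i][None], loss_cfg, 1.0,
                                epoch_seed + int(i), train=False, rng=None)
            totals += float(terms.total.data)
            frames += lengths[i]
        return -totals / max(frames, 1)

    for epoch in range(cfg.n_epochs):
        w = anneal_weight(epoch, cfg)
        epoch_terms = []
        for batch in _batches(train_idx, lengths, cfg.batch_sequences, rng):
            x = np.stack([xs[i] for i in batch])
            labels = np.stack([ys[i] for i in batch])
            step_seed = int(rng.integers(2 ** 31))
            terms = _loss_terms(cfg.model_kind, posterior, gen_params, x,
                                labels, loss_cfg, w, step_seed, train=True,
                                rng=dropout_rng)
            loss = -terms.total * (1.0 / x[..., 0].size)
            if not np.isfinite(loss.data):
                bad = [k for k, v in terms.as_floats().items()
                       if not np.isfinite(v)]
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; offending terms: {bad}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            row = terms.as_floats()
            row["loss"] = float(loss.data)
            epoch_terms.append(row)
        mean_row = {k: float(np.mean([r[k] for r in epoch_terms]))
                    for k in epoch_terms[0]}
        mean_row["epoch"] = epoch
        mean_row["anneal_w"] = w
        state.history.append(mean_row)
        state.epoch = epoch + 1

        last = epoch == cfg.n_epochs - 1
        if n_val and (epoch % cfg.val_every == 0 or last):
            val_loss = evaluate_val(cfg.seed * 1000 + epoch)
            state.val_history.append({"epoch": epoch, "val_loss": val_loss})
            if val_loss < state.best_val:
                state.best_val = val_loss
                state.best_arrays = snapshot()

    if state.best_arrays is not None:
        for p, a in zip(params, state.best_arrays):
            p.data = a.copy()
    return state
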