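"""Metric suite: per-class F1 and confusion, TP/FP predictive entropy,
majority-overlap matching of unsupervised states to behavior classes, and
cluster homogeneity of latent embeddings.

Only frames carrying a ground-truth class label are ever scored;
background and unlabeled frames are excluded throughout.  Entropies use
the natural logarithm, so the uniform upper bound is ln K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import confusion_matrix, homogeneity_score, \
    precision_recall_fscore_support

from .features import LabelSequence

UNMATCHED = -1


@dataclass
class EvalReport:
    class_names: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    confusion: np.ndarray                      # rows = truth
    tp_entropy: dict = field(default_factory=dict)   # class -> mean entropy
    fp_entropy: dict = field(default_factory=dict)
    homogeneity: dict = field(default_factory=dict)  # n_clusters -> score

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "tp_entropy": {str(k): v for k, v in self.tp_entropy.items()},
            "fp_entropy": {str(k): v for k, v in self.fp_entropy.items()},
            "homogeneity": {str(k): v for k, v in self.homogeneity.items()},
        }


def _scored_frames(pred: np.ndarray, labels: LabelSequence):
    mask = labels.labeled_mask
    if not mask.any():
        raise ValueError("empty labeled set")
    return np.asarray(pred)[mask], labels.labels[mask]


def f1_report(pred: np.ndarray, labels: LabelSequence) -> EvalReport:
    """Per-class precision/recall/F1 (F1 = 0 when precision+recall = 0),
    macro-F1 as the unweighted class mean, and the confusion matrix."""
    yhat, y = _scored_frames(pred, labels)
    K = labels.n_classes
    p, r, f1, _ = precision_recall_fscore_support(
        y, yhat, labels=np.arange(K), zero_division=0)
    conf = confusion_matrix(y, yhat, labels=np.arange(K))
    return EvalReport(list(labels.class_names), p, r, f1, float(np.mean(f1)), conf)


def entropy_report(class_probs: np.ndarray, pred: np.ndarray,
                   labels: LabelSequence) -> tuple[dict, dict]:
    """Mean Shannon entropy (nats) of the classifier rows, per predicted
    class, split into true positives and false positives.

    Empty TP/FP sets are reported as absent keys, not zeros.
    """
    mask = labels.labeled_mask
    probs = np.asarray(class_probs, float)[mask]
    yhat = np.asarray(pred)[mask]
    y = labels.labels[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(probs > 0, probs * np.log(probs), 0.0), axis=-1)
    tp, fp = {}, {}
    for k in range(labels.n_classes):
        tp_set = (yhat == k) & (y == k)
        fp_set = (yhat == k) & (y != k)
        if tp_set.any():
            tp[k] = float(ent[tp_set].mean())
        if fp_set.any():
            fp[k] = float(ent[fp_set].mean())
    return tp, fp


def match_states(pred_states: np.ndarray, labels: LabelSequence) -> dict:
    """Map each predicted state (arbitrary alphabet) to the behavior class
    with the largest co-occurrence count on labeled frames.

    Many-to-one is allowed; ties break to the lowest class index; states
    never seen on labeled frames map to UNMATCHED (-1).
    """
    states, y = _scored_frames(pred_states, labels)
    mapping = {}
    for s in np.unique(np.asarray(pred_states)):
        on_labeled = y[states == s]
        if on_labeled.size == 0:
            mapping[int(s)] = UNMATCHED
            continue
        counts = np.bincount(on_labeled, minlength=labels.n_classes)
        mapping[int(s)] = int(np.argmax(counts))  # argmax takes lowest on ties
    return mapping


def apply_state_map(pred_states: np.ndarray, mapping: dict) -> np.ndarray:
    return np.asarray([mapping.get(int(s), UNMATCHED) for s in pred_states])


def homogeneity(cluster_ids: np.ndarray, class_ids: np.ndarray) -> float:
    """h = 1 - H(class | cluster) / H(class); 1 when H(class) = 0."""
    cluster_ids = np.asarray(cluster_ids)
    class_ids = np.asarray(class_ids)
    if cluster_ids.size == 0 or cluster_ids.shape != class_ids.shape:
        raise ValueError("need equal-length non-empty id vectors")
    return float(homogeneity_score(class_ids, cluster_ids))


def latent_cluster_scores(latents: np.ndarray, labels: LabelSequence,
                          cluster_counts, seed: int = 0) -> dict:
    """K-means (10 restarts, seeded) over the latent embedding for each
    requested cluster count; homogeneity is scored on labeled frames only
    (clustering itself uses every frame)."""
    latents = np.asarray(latents, float)
    scores = {}
    mask = labels.labeled_mask
    if not mask.any():
        raise ValueError("empty labeled set")
    for n in cluster_counts:
        if n > latents.shape[0]:
            raise ValueError(f"cluster count {n} exceeds {latents.shape[0]} points")
        km = KMeans(n_clusters=int(n), n_init=10, random_state=seed)
        assign = km.fit_predict(latents)
        scores[int(n)] = homogeneity(assign[mask], labels.labels[mask])
    return scores
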