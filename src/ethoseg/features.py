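"""Behavioral feature / label containers, file I/O, and feature engineering.

A session is a pair of a :class:`FeatureSequence` (T x D per-frame feature
matrix, e.g. pose coordinates or derived kinematic features) and a
:class:`LabelSequence` (per-frame discrete behavior labels with sentinels
for unlabeled and background frames).

Feature engineering follows the position-velocity recipe: the pose vector
x_t is concatenated with its first difference x_t - x_{t-1}, and the
continuous latent dimensionality is chosen as the smallest number of
principal components explaining a target fraction of variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

UNLABELED = -1
BACKGROUND = -2


@dataclass
class FeatureSequence:
    """One session's T x D feature matrix."""

    values: np.ndarray
    frame_rate_hz: float = 1.0
    feature_names: list[str] = field(default_factory=list)
    session_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x D matrix")
        T, D = self.values.shape
        if T < 1 or D < 1:
            raise ValueError("need T >= 1 and D >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(D)]
        if len(self.feature_names) != D:
            raise ValueError("feature_names length must equal D")
        if len(set(self.feature_names)) != D:
            raise ValueError("feature_names must be unique")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelSequence:
    """Per-frame labels in {0..K-1} plus UNLABELED (-1) / BACKGROUND (-2)."""

    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a vector")
        K = len(self.class_names)
        bad = self.labels[(self.labels >= K) | (self.labels < BACKGROUND)]
        if bad.size:
            raise ValueError(f"label value {bad[0]} out of range for K={K}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def labeled_mask(self) -> np.ndarray:
        """Frames in the labeled set (background counts as unlabeled)."""
        return self.labels >= 0

    @property
    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labeled_mask)

    @property
    def unlabeled_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.labeled_mask)


# -- file I/O ----------------------------------------------------------------

def read_features(path, dialect: str = "plain", frame_rate_hz: float = 1.0,
                  session_id: str = "") -> FeatureSequence:
    """Read a feature CSV.

    dialect="plain": one header row then T x D numeric rows.
    dialect="dlc":   DeepLabCut three-row header (scorer/bodyparts/coords);
                     likelihood columns are dropped so D = 2 * n_keypoints.
    """
    if dialect == "plain":
        df = pd.read_csv(path)
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no data rows")
        values = df.to_numpy(dtype=np.float64)
        names = [str(c) for c in df.columns]
    elif dialect == "dlc":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no data rows")
        coords = df.columns.get_level_values(2)
        if not set(coords) <= {"x", "y", "likelihood"}:
            raise ValueError(f"{path}: malformed DeepLabCut header")
        keep = [c for c in df.columns if c[2] != "likelihood"]
        df = df[keep]
        values = df.to_numpy(dtype=np.float64)
        names = [f"{c[1]}_{c[2]}" for c in df.columns]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return FeatureSequence(values, frame_rate_hz=frame_rate_hz,
                           feature_names=names,
                           session_id=session_id or str(path))


def write_features(path, fs: FeatureSequence) -> None:
    """Write a plain-dialect feature CSV (header + numeric rows)."""
    pd.DataFrame(fs.values, columns=fs.feature_names).to_csv(path, index=False)


def read_labels(path, class_names: list[str]) -> LabelSequence:
    """Read a single-column CSV of integer labels (-1 unlabeled, -2 background)."""
    df = pd.read_csv(path, header=None)
    values = df.iloc[:, 0].to_numpy()
    as_int = values.astype(np.int64)
    if not np.array_equal(as_int, values.astype(np.float64)):
        raise ValueError(f"{path}: non-integer label entry")
    return LabelSequence(as_int, class_names=list(class_names))


def write_labels(path, ls: LabelSequence) -> None:
    pd.DataFrame(ls.labels).to_csv(path, index=False, header=False)


# -- feature engineering -----------------------------------------------------

def add_velocity(fs: FeatureSequence) -> FeatureSequence:
    """Concatenate each frame's features with their first difference.

    The frame-0 velocity is the zero vector (exact for a still start),
    keeping T unchanged.  Output dimensionality is 2 D.
    """
    vel = np.zeros_like(fs.values)
    vel[1:] = fs.values[1:] - fs.values[:-1]
    names = list(fs.feature_names) + [n + "_vel" for n in fs.feature_names]
    return FeatureSequence(np.hstack([fs.values, vel]),
                           frame_rate_hz=fs.frame_rate_hz,
                           feature_names=names, session_id=fs.session_id)


def choose_latent_dim(fs: FeatureSequence, threshold: float = 0.95) -> int:
    """Smallest number of principal components explaining >= `threshold`
    of the total variance of the (column-centered) features."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    values = fs.values - fs.values.mean(axis=0)
    total = np.var(values, axis=0).sum()
    if total <= 0:
        raise ValueError("zero total variance")
    n_comp = min(values.shape[0], values.shape[1])
    pca = PCA(n_components=n_comp)
    pca.fit(values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return min(d, n_comp)


class Standardizer:
    """Per-column z-scoring with statistics frozen on the training split."""

    def __init__(self, mean: np.ndarray | None = None, std: np.ndarray | None = None):
        self.mean = mean
        self.std = std

    def fit(self, matrices: list[np.ndarray]) -> "Standardizer":
        stacked = np.vstack(matrices)
        self.mean = stacked.mean(axis=0)
        std = stacked.std(axis=0)
        self.std = np.where(std > 1e-12, std, 1.0)
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std

    def transform_sequence(self, fs: FeatureSequence) -> FeatureSequence:
        return replace(fs, values=self.transform(fs.values))


def mask_labels(labels: np.ndarray, labeled_fraction: float, seed: int,
                bout_length: int = 100) -> np.ndarray:
    """Keep contiguous labeled bouts covering ~`labeled_fraction` of frames,
    setting the rest to UNLABELED.

    Mirrors how annotators label behavioral video in contiguous chunks
    rather than isolated frames.
    """
    T = len(labels)
    out = np.full(T, UNLABELED, dtype=np.int64)
    if labeled_fraction >= 1.0:
        return labels.copy()
    if labeled_fraction <= 0.0:
        return out
    rng = np.random.default_rng(seed)
    target = int(round(labeled_fraction * T))
    n_bouts = max(1, target // bout_length)
    starts = rng.choice(max(T - bout_length, 1), size=n_bouts, replace=False)
    kept = 0
    for s in np.sort(starts):
        e = min(s + bout_length, T)
        out[s:e] = labels[s:e]
        kept += e - s
        if kept >= target:
            break
    return out
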