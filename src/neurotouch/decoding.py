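"""Rate-coding readout: spike counts -> PCA (3 PCs) -> kNN (k = 5).

The decoder follows the classic rate-coding paradigm: each afferent's
response in a trial is summarized by its firing rate FR = spikes / dt over
the counting window (by default the whole trial).  Trial feature vectors are
z-scored per feature on the training folds, projected onto the first three
principal components, and classified by a k-nearest-neighbour vote with
k = 5.  Performance is reported as mean +/- SD accuracy over stratified
5-fold cross-validation (each fold trains on 80% of the trials and tests on
the held-out 20%), separately per afferent type (SA-I, FA-I, both) and per
finger condition (3, 4, 5) -- a 3x3 result table.

Scaling and PCA are fitted on training folds only and applied to the test
fold, so no test statistics leak into the fit.  kNN ties are broken in
favour of the tied class with the smallest mean neighbour distance.  Besides
majority-vote kNN, a nearest-class-mean rule is available as an alternative
classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .stimulus import TrialSet

__all__ = [
    "FeatureMatrix", "DecoderConfig", "PcaReduction", "DecodingReport",
    "spike_counts", "reduce_pca", "knn_classify", "nearest_class_mean",
    "evaluate",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-trial spike-count features with labels and unit metadata."""

    X: np.ndarray              # (n_trials, n_units) non-negative counts
    labels: np.ndarray
    conditions: np.ndarray
    unit_ids: Tuple[str, ...]
    unit_types: np.ndarray
    window: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ValueError("feature matrix rows must match labels")
        if np.any(self.X < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def dt_s(self) -> float:
        return (self.window[1] - self.window[0]) / 1000.0

    def rates(self) -> np.ndarray:
        """Firing rates FR = spikes / dt in Hz."""
        return self.X / self.dt_s


def spike_counts(trials: TrialSet, window: Optional[Tuple[float, float]] = None,
                 type_filter: str = "both") -> FeatureMatrix:
    """Count spikes per afferent per trial in a window.

    ``type_filter`` restricts the feature columns to SA-I, FA-I or both.
    """
    mask = trials.type_mask(type_filter)
    if not np.any(mask):
        raise ValueError(f"type filter {type_filter!r} selects no afferents")
    win = window if window is not None else (0.0, trials.duration)
    X = trials.counts(window=win, type_filter=type_filter)
    unit_ids = tuple(u for u, m in zip(trials.unit_ids, mask) if m)
    return FeatureMatrix(X=X, labels=np.asarray(trials.labels),
                         conditions=np.asarray(trials.conditions),
                         unit_ids=unit_ids,
                         unit_types=trials.unit_types[mask], window=win)


@dataclass(frozen=True)
class DecoderConfig:
    """Decoder hyper-parameters (defaults reproduce the reference pipeline)."""

    n_components: int = 3
    k_neighbors: int = 5
    train_fraction: float = 0.8
    cv_folds: int = 5
    normalize: bool = True
    classifier: str = "knn"   # "knn" or "class-mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.classifier not in ("knn", "class-mean"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass(frozen=True)
class PcaReduction:
    """Fitted normalization + projection onto the top principal components."""

    scores: np.ndarray
    components: np.ndarray             # (n_components, n_kept_features)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    kept: np.ndarray                   # indices of non-degenerate features

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=np.float64)[:, self.kept] - self.mean) / self.scale
        return Z @ self.components.T


def _fit_pca(X: np.ndarray, n_components: int, normalize: bool) -> PcaReduction:
    X = np.asarray(X, dtype=np.float64)
    std = X.std(axis=0)
    kept = np.flatnonzero(std > 0)
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} zero-variance feature(s) "
            "before PCA", stacklevel=3)
    if kept.size == 0:
        raise ValueError("all features have zero variance")
    mean = X[:, kept].mean(axis=0)
    scale = std[kept] if normalize else np.ones(kept.size)
    Z = (X[:, kept] - mean) / scale
    n_comp = min(n_components, Z.shape[0] - 1, Z.shape[1])
    if n_comp < 1:
        raise ValueError("need at least 2 trials for PCA")
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z)
    components = pca.components_
    # Deterministic orientation: largest-|loading| entry of each PC positive.
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    return PcaReduction(scores=scores, components=components,
                        explained_variance_ratio=pca.explained_variance_ratio_,
                        mean=mean, scale=scale, kept=kept)


def reduce_pca(features, n_components: int = 3,
               normalize: bool = True) -> PcaReduction:
    """Project normalized spike-count features onto the top principal axes.

    Accepts a :class:`FeatureMatrix` or a plain 2-D array.  Features are
    centred (and by default unit-scaled); zero-variance features are dropped
    with a warning.  Component signs follow a largest-loading-positive
    convention, so the decomposition is fully deterministic.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 trials for a 3-component projection")
    return _fit_pca(X, n_components, normalize)


def knn_classify(train_scores: np.ndarray, train_labels: np.ndarray,
                 test_scores: np.ndarray, k: int = 5) -> np.ndarray:
    """Majority vote among the k Euclidean-nearest training points.

    Vote ties are broken in favour of the tied class whose voting neighbours
    lie closest on average; any remaining tie falls to the lexicographically
    smallest label (fully deterministic).
    """
    train_scores = np.atleast_2d(np.asarray(train_scores, dtype=np.float64))
    test_scores = np.atleast_2d(np.asarray(test_scores, dtype=np.float64))
    train_labels = np.asarray(train_labels)
    n_train = train_scores.shape[0]
    if k > n_train:
        raise ValueError(f"k={k} exceeds the training-set size {n_train}")
    dists = cdist(test_scores, train_scores)
    order = np.argsort(dists, axis=1, kind="stable")[:, :k]
    predictions = []
    for row, nn in zip(dists, order):
        nn_labels = train_labels[nn]
        classes, votes = np.unique(nn_labels, return_counts=True)
        top = votes.max()
        tied = classes[votes == top]
        if tied.size == 1:
            predictions.append(tied[0])
            continue
        mean_d = [row[nn[nn_labels == cls]].mean() for cls in tied]
        predictions.append(tied[int(np.argmin(mean_d))])
    return np.asarray(predictions)


def nearest_class_mean(train_scores: np.ndarray, train_labels: np.ndarray,
                       test_scores: np.ndarray) -> np.ndarray:
    """Assign each test point to the class with the nearest centroid.

    This is the alternative reading of the reference decoding rule ("smallest
    mean difference to the spike trains of a class"); the primary classifier
    remains the kNN vote.
    """
    train_scores = np.atleast_2d(np.asarray(train_scores, dtype=np.float64))
    test_scores = np.atleast_2d(np.asarray(test_scores, dtype=np.float64))
    train_labels = np.asarray(train_labels)
    classes = np.unique(train_labels)
    centroids = np.stack([train_scores[train_labels == c].mean(axis=0)
                          for c in classes])
    return classes[np.argmin(cdist(test_scores, centroids), axis=1)]


@dataclass
class DecodingReport:
    """Mean +/- SD cross-validated accuracy per afferent type and condition."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    fold_accuracies: Dict[Tuple[str, int], np.ndarray]
    config: DecoderConfig

    def accuracy(self, type_filter: str, condition: int) -> float:
        return float(self.mean.loc[_row_name(type_filter), condition])

    def to_dataframe(self) -> pd.DataFrame:
        """Formatted table, cells "mean% +/- sd%"."""
        out = self.mean.copy().astype(object)
        for r in out.index:
            for c in out.columns:
                out.loc[r, c] = (f"{self.mean.loc[r, c] * 100:.0f}% "
                                 f"± {self.sd.loc[r, c] * 100:.0f}%")
        out.columns = [f"{c}-finger" for c in out.columns]
        return out

    def to_json_dict(self) -> dict:
        return {
            "mean": {r: {int(c): float(self.mean.loc[r, c])
                         for c in self.mean.columns}
                     for r in self.mean.index},
            "sd": {r: {int(c): float(self.sd.loc[r, c])
                       for c in self.sd.columns}
                   for r in self.sd.index},
        }


_ROW_NAMES = {"SA": "SA-I", "FA": "FA-I", "both": "Both (SA-I and FA-I)"}


def _row_name(type_filter: str) -> str:
    token = type_filter if type_filter == "both" else \
        type_filter.upper().replace("-I", "")
    return _ROW_NAMES[token]


def _cv_fold_accuracies(X: np.ndarray, y: np.ndarray,
                        config: DecoderConfig) -> np.ndarray:
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        reduction = _fit_pca(X[train_idx], config.n_components, config.normalize)
        train_scores = reduction.scores
        test_scores = reduction.transform(X[test_idx])
        if config.classifier == "knn":
            pred = knn_classify(train_scores, y[train_idx], test_scores,
                                k=config.k_neighbors)
        else:
            pred = nearest_class_mean(train_scores, y[train_idx], test_scores)
        accs.append(float(np.mean(pred == y[test_idx])))
    return np.asarray(accs)


def evaluate(trials: TrialSet,
             config: DecoderConfig = DecoderConfig()) -> DecodingReport:
    """Cross-validated decoding accuracy per afferent type and condition.

    For each of {SA-I, FA-I, both} x finger conditions, the trials of that
    condition are decoded under stratified ``cv_folds``-fold cross-validation
    (each fold holds out ``1 - train_fraction`` of the trials; stratification
    guarantees every class is present in every fold).  Normalization and PCA
    are refitted on each training fold.
    """
    conditions = sorted(set(int(c) for c in trials.conditions))
    if np.unique(trials.labels).size < 2:
        raise ValueError("need at least two classes to decode")
    type_filters = ("SA", "FA", "both")
    mean = pd.DataFrame(index=[_row_name(tf) for tf in type_filters],
                        columns=conditions, dtype=float)
    sd = mean.copy()
    folds: Dict[Tuple[str, int], np.ndarray] = {}
    for tf in type_filters:
        fm = spike_counts(trials, type_filter=tf)
        for cond in conditions:
            sel = np.flatnonzero(fm.conditions == cond)
            accs = _cv_fold_accuracies(fm.X[sel], fm.labels[sel], config)
            folds[(tf, cond)] = accs
            mean.loc[_row_name(tf), cond] = accs.mean()
            sd.loc[_row_name(tf), cond] = accs.std(ddof=1)
    return DecodingReport(mean=mean, sd=sd, fold_accuracies=folds,
                          config=config)
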