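"""Classifiers for two-variety spectral discrimination.

Three model families, matching common chemometrics practice:

* RBF-kernel SVM with (C, gamma) chosen by exhaustive grid search over
  2^-8..2^8 (log2 step configurable) scored by stratified k-fold
  cross-validated accuracy; ties resolve to the smaller C, then smaller
  gamma, and the winner is refit on all rows.
* k-nearest neighbours on Euclidean distance, with deterministic tie
  handling: equidistant training rows enter in index order, and a tied vote
  falls back to the class of the single nearest neighbour.
* RBF network: one Gaussian hidden unit centred on every training row with a
  common spread, read out by ridge-regularised least squares onto one-hot
  labels (exact interpolation as ridge -> 0 for distinct rows).

Also provides representative-pixel selection: k-means the (typically huge)
pixel calibration set into ``n_groups`` clusters and keep, per cluster, the
row nearest its centroid — shrinking the set while covering its spectral
diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "KNNConfig",
    "RBFNNConfig",
    "TrainedClassifier",
    "grid_search_svm",
    "train_knn",
    "train_rbfnn",
    "select_representative_pixels",
    "RepresentativeSelection",
]


@dataclass
class SVMConfig:
    log2_c_range: tuple[float, float] = (-8.0, 8.0)
    log2_gamma_range: tuple[float, float] = (-8.0, 8.0)
    log2_step: float = 1.0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")
        for lo, hi in (self.log2_c_range, self.log2_gamma_range):
            if not (-8.0 <= lo <= hi <= 8.0):
                raise ValueError("grid must lie within 2^-8 .. 2^8")

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        def axis(lo: float, hi: float) -> np.ndarray:
            return 2.0 ** np.arange(lo, hi + 1e-9, self.log2_step)

        return axis(*self.log2_c_range), axis(*self.log2_gamma_range)


@dataclass
class KNNConfig:
    k: int = 3
    weighting: str = "uniform"  # or "inverse"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.weighting not in ("uniform", "inverse"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass
class RBFNNConfig:
    spread: float | None = None  # None -> median pairwise training distance
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.spread is not None and self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


@dataclass
class TrainedClassifier:
    """A fitted model plus the metadata needed to refuse mismatched inputs."""

    kind: str  # svm | knn | rbfnn
    params: dict
    n_features: int
    classes: np.ndarray
    _state: dict = field(repr=False, default_factory=dict)
    feature_wavelengths: np.ndarray | None = None
    stage: str | None = None
    seed: int | None = None

    def _check(self, X: np.ndarray, stage: str | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"{self.kind} model expects {self.n_features} features, "
                f"got array of shape {X.shape}"
            )
        if stage is not None and self.stage is not None and stage != self.stage:
            raise ValueError(
                f"model was trained on stage {self.stage!r}, got {stage!r}"
            )
        return X

    def predict(self, X: np.ndarray, stage: str | None = None) -> np.ndarray:
        X = self._check(X, stage)
        if self.kind == "svm":
            return self._state["svc"].predict(X)
        if self.kind == "knn":
            return _knn_predict(X, **self._state)
        if self.kind == "rbfnn":
            return _rbfnn_predict(X, **self._state)
        raise ValueError(f"unknown model kind {self.kind!r}")


# ---------------------------------------------------------------------------
# SVM


def grid_search_svm(
    X: np.ndarray,
    y: Sequence,
    config: SVMConfig | None = None,
    seed: int = 0,
    **train_meta,
) -> tuple[float, float, TrainedClassifier]:
    """Exhaustive (C, gamma) grid search with stratified CV, then refit.

    Returns the winning pair and the refit classifier.  The grid and the fold
    partition are fully determined by ``config`` and ``seed``.
    """
    config = config or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("grid search needs at least two classes")
    folds = min(config.cv_folds, int(np.min(np.unique(y, return_counts=True)[1])))
    if folds < 2:
        raise ValueError("too few rows per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    cs, gammas = config.grid()
    best = (-1.0, None, None)
    for c in cs:  # ascending, so strict improvement keeps the smallest C/gamma
        for g in gammas:
            correct = total = 0
            for tr, te in splits:
                svc = SVC(C=c, gamma=g, kernel="rbf")
                svc.fit(X[tr], y[tr])
                correct += int(np.sum(svc.predict(X[te]) == y[te]))
                total += len(te)
            acc = correct / total
            if acc > best[0]:
                best = (acc, c, g)
    _, c, g = best
    svc = SVC(C=c, gamma=g, kernel="rbf")
    svc.fit(X, y)
    clf = TrainedClassifier(
        kind="svm",
        params={"C": float(c), "gamma": float(g), "cv_accuracy": best[0], "cv_folds": folds},
        n_features=X.shape[1],
        classes=classes,
        _state={"svc": svc},
        seed=seed,
        **train_meta,
    )
    return float(c), float(g), clf


# ---------------------------------------------------------------------------
# k-NN


def _knn_predict(
    X: np.ndarray, train_X=None, train_y=None, k=3, weighting="uniform"
) -> np.ndarray:
    dists = cdist(X, train_X)
    # stable sort: equidistant training rows enter in index order
    order = np.argsort(dists, axis=1, kind="stable")[:, :k]
    preds = np.empty(len(X), dtype=train_y.dtype)
    for i in range(len(X)):
        nbrs = order[i]
        labels = train_y[nbrs]
        if weighting == "inverse":
            w = 1.0 / np.maximum(dists[i, nbrs], 1e-12)
        else:
            w = np.ones(len(nbrs))
        classes, inv = np.unique(labels, return_inverse=True)
        votes = np.bincount(inv, weights=w, minlength=len(classes))
        top = np.nonzero(votes == votes.max())[0]
        if len(top) == 1:
            preds[i] = classes[top[0]]
        else:  # tied vote -> class of the single nearest neighbour
            preds[i] = train_y[nbrs[0]]
    return preds


def train_knn(
    X: np.ndarray, y: Sequence, config: KNNConfig | None = None, **train_meta
) -> TrainedClassifier:
    config = config or KNNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if config.k > len(X):
        raise ValueError(f"k={config.k} exceeds the {len(X)} training rows")
    return TrainedClassifier(
        kind="knn",
        params={"k": config.k, "weighting": config.weighting},
        n_features=X.shape[1],
        classes=np.unique(y),
        _state={
            "train_X": X.copy(),
            "train_y": y.copy(),
            "k": config.k,
            "weighting": config.weighting,
        },
        **train_meta,
    )


# ---------------------------------------------------------------------------
# RBF network


def _rbfnn_predict(X, centers=None, weights=None, spread=None, classes=None):
    K = np.exp(-cdist(X, centers, "sqeuclidean") / (2.0 * spread**2))
    return classes[np.argmax(K @ weights, axis=1)]


def train_rbfnn(
    X: np.ndarray, y: Sequence, config: RBFNNConfig | None = None, **train_meta
) -> TrainedClassifier:
    """Exact RBF expansion (one Gaussian unit per training row) with a ridge
    least-squares readout onto one-hot labels.  Deterministic closed form.

    With ``spread=None`` the Gaussian width defaults to the median pairwise
    training distance, a standard scale heuristic.
    """
    config = config or RBFNNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    D2 = cdist(X, X, "sqeuclidean")
    if config.spread is None:
        off = D2[np.triu_indices(len(X), k=1)]
        spread = float(np.sqrt(np.median(off))) if off.size else 1.0
        if spread <= 0:
            spread = 1.0
    else:
        spread = float(config.spread)
    K = np.exp(-D2 / (2.0 * spread**2))
    onehot = (y[:, None] == classes[None, :]).astype(float)
    A = K + config.ridge * np.eye(len(X))
    try:
        weights = np.linalg.solve(A, onehot)
    except np.linalg.LinAlgError:
        weights = np.linalg.lstsq(A, onehot, rcond=None)[0]
    return TrainedClassifier(
        kind="rbfnn",
        params={"spread": spread, "ridge": config.ridge},
        n_features=X.shape[1],
        classes=classes,
        _state={
            "centers": X.copy(),
            "weights": weights,
            "spread": spread,
            "classes": classes,
        },
        **train_meta,
    )


# ---------------------------------------------------------------------------
# Representative-pixel selection


@dataclass
class RepresentativeSelection:
    """k-means representative subset: unique row indices, one per non-empty
    cluster (the member nearest its centroid)."""

    indices: np.ndarray
    cluster_labels: np.ndarray
    centroids: np.ndarray
    n_groups: int


def select_representative_pixels(
    X: np.ndarray, n_groups: int = 3000, seed: int = 0
) -> RepresentativeSelection:
    """Shrink a pixel set to at most ``n_groups`` representatives.

    If the set already has at most ``n_groups`` rows it is returned whole.
    Otherwise k-means (k-means++ init, 10 restarts, fixed seed) partitions
    the rows and each cluster contributes its nearest-to-centroid member.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be at least 1")
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n <= n_groups:
        return RepresentativeSelection(
            indices=np.arange(n),
            cluster_labels=np.arange(n),
            centroids=X.copy(),
            n_groups=n,
        )
    km = KMeans(n_clusters=n_groups, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    indices = []
    for c in range(n_groups):
        members = np.nonzero(labels == c)[0]
        if members.size == 0:
            continue
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        indices.append(members[int(np.argmin(d))])
    return RepresentativeSelection(
        indices=np.array(sorted(indices), dtype=int),
        cluster_labels=labels,
        centroids=km.cluster_centers_,
        n_groups=n_groups,
    )
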