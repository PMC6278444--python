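"""Effective-wavelength selection by PCA loadings and FastICA unmixing weights.

Hyperspectral NIR bands are highly collinear; a handful of "effective
wavelengths" usually carries the discriminative signal.  Two selectors are
provided:

* **PCA loadings** — fit PCA on (object- or pixel-wise) spectra, score each
  band by the maximum absolute loading it attains across the retained
  components (default 7, the number that explains >99% of variance in
  practice on this kind of data), keep bands that are local maxima of that
  score profile, and take the top ``n_select``.
* **ICA weights** — fit FastICA (X = A s, s_hat = W X); score each band by
  the mean absolute unmixing weight across independent components and take
  the top ``n_select``.

How multiple components are combined into one ranked list is a documented
package choice (the max-over-components, local-peak rule for PCA); both
selectors break ties toward the lower wavelength and report the selected
bands sorted ascending in wavelength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .cubes import HyperspectralCube, ObjectMask

__all__ = [
    "PCAModel",
    "ICAModel",
    "WavelengthSelectionResult",
    "pca_fit",
    "ica_fit",
    "scores_image",
    "select_by_pca_loadings",
    "select_by_ica_weights",
]


@dataclass
class PCAModel:
    """Fitted PCA: bands x k loadings (orthonormal columns), row scores,
    non-increasing explained-variance ratios and the mean spectrum."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    wavelengths: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ICAModel:
    """Fitted FastICA.  ``unmixing @ (X - mean).T`` reproduces the estimated
    sources; ``mixing`` is its pseudo-inverse (X = A s convention)."""

    mixing: np.ndarray  # bands x k
    unmixing: np.ndarray  # k x bands
    sources: np.ndarray  # rows x k
    mean: np.ndarray
    n_components: int
    seed: int
    n_iter: int
    wavelengths: np.ndarray | None = None


@dataclass
class WavelengthSelectionResult:
    """Ordered effective-wavelength list with per-band diagnostic scores."""

    method: str
    band_indices: np.ndarray  # sorted ascending
    wavelengths: np.ndarray
    scores: np.ndarray  # per-band score profile, length = bands
    n_requested: int

    def __post_init__(self) -> None:
        self.band_indices = np.asarray(self.band_indices, dtype=int)
        if len(self.band_indices) != self.n_requested:
            raise ValueError("selection cardinality must equal n_requested")
        if len(np.unique(self.band_indices)) != len(self.band_indices):
            raise ValueError("selected band indices must be unique")
        if np.any(np.diff(self.band_indices) <= 0):
            raise ValueError("selected bands must be sorted ascending")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "band_index": self.band_indices,
                "score": self.scores[self.band_indices],
                "method": self.method,
            }
        ).to_csv(path, index=False)
        return path

    def write_provenance(self, path: str | Path, **params) -> Path:
        path = Path(path)
        path.write_text(
            yaml.safe_dump({"method": self.method, "n_requested": self.n_requested, **params})
        )
        return path


def pca_fit(
    X: np.ndarray, n_components: int, wavelengths: np.ndarray | None = None
) -> PCAModel:
    """Principal component analysis of a rows x bands spectra matrix."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= n_components:
        raise ValueError(
            f"need more rows ({X.shape[0]}) than components ({n_components})"
        )
    rank = np.linalg.matrix_rank(X - X.mean(axis=0)) if min(X.shape) <= 512 else min(X.shape)
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but data rank is {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAModel(
        loadings=pca.components_.T,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def ica_fit(
    X: np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    wavelengths: np.ndarray | None = None,
) -> ICAModel:
    """FastICA decomposition X = A s with a fixed seed.

    Raises on non-convergence (reporting the iteration budget) instead of
    silently returning a partially converged unmixing matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= n_components:
        raise ValueError(
            f"need more rows ({X.shape[0]}) than components ({n_components})"
        )
    rank = np.linalg.matrix_rank(X - X.mean(axis=0)) if min(X.shape) <= 512 else min(X.shape)
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but data rank is {rank}")
    ica = FastICA(
        n_components=n_components,
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            sources = ica.fit_transform(X)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"FastICA did not converge within {max_iter} iterations"
            ) from exc
    return ICAModel(
        mixing=ica.mixing_,
        unmixing=ica.components_,
        sources=sources,
        mean=ica.mean_,
        n_components=n_components,
        seed=seed,
        n_iter=int(ica.n_iter_),
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def scores_image(
    model: PCAModel,
    cube: HyperspectralCube,
    objmask: ObjectMask,
    pc: int,
    preprocess: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Raster of per-pixel scores on one principal component.

    Background pixels are NaN; each foreground pixel is the projection of its
    (optionally preprocessed) spectrum onto the requested component.  The
    ``preprocess`` callable must reproduce the stage the model was fit on.
    """
    if not (1 <= pc <= model.n_components):
        raise ValueError(f"pc must be in 1..{model.n_components}, got {pc}")
    out = np.full(cube.shape[:2], np.nan)
    rr, cc = np.nonzero(objmask.labels > 0)
    if rr.size == 0:
        return out
    spectra = cube.data[rr, cc, :]
    if preprocess is not None:
        spectra = preprocess(spectra)
    out[rr, cc] = (spectra - model.mean) @ model.loadings[:, pc - 1]
    return out


def _local_peak_runs(score: np.ndarray) -> np.ndarray:
    """Indices of local maxima of a 1-D profile; a plateau counts once, at its
    lowest-index (lowest-wavelength) band.  Boundary runs qualify when they
    exceed their single inner neighbour."""
    n = len(score)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and score[j + 1] == score[i]:
            j += 1
        left_ok = i == 0 or score[i - 1] < score[i]
        right_ok = j == n - 1 or score[j + 1] < score[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return np.array(peaks, dtype=int)


def _rank_and_sort(
    candidates: np.ndarray, score: np.ndarray, n_select: int
) -> np.ndarray:
    """Top ``n_select`` candidate bands by score, ties to lower index; filled
    from non-candidate bands by the same ordering when candidates run out."""
    bands = len(score)
    if n_select > bands:
        raise ValueError(f"cannot select {n_select} of {bands} bands")
    order = candidates[np.lexsort((candidates, -score[candidates]))]
    chosen = list(order[:n_select])
    if len(chosen) < n_select:
        rest = np.setdiff1d(np.arange(bands), candidates)
        rest = rest[np.lexsort((rest, -score[rest]))]
        chosen.extend(rest[: n_select - len(chosen)])
    return np.sort(np.array(chosen, dtype=int))


def select_by_pca_loadings(
    model: PCAModel,
    n_select: int = 20,
    n_pcs: int = 7,
    wavelengths: np.ndarray | None = None,
) -> WavelengthSelectionResult:
    """Effective wavelengths from PCA loadings.

    Band score = max over the first ``n_pcs`` components of the
    variance-scaled absolute loading ``sqrt(evr_j) * |l_jb|`` — the classic
    chemometric loading convention (eigenvector times the square root of its
    eigenvalue share), which keeps a low-variance component from outranking
    the dominant ones.  Candidate bands are local maxima of the score
    profile, so neighbouring shoulders of one absorbance feature collapse to
    a single pick.
    """
    if n_pcs > model.n_components:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds fitted components ({model.n_components})"
        )
    weights = np.sqrt(model.explained_variance_ratio[:n_pcs])
    score = np.max(np.abs(model.loadings[:, :n_pcs]) * weights, axis=1)
    peaks = _local_peak_runs(score)
    chosen = _rank_and_sort(peaks, score, n_select)
    wl = wavelengths if wavelengths is not None else model.wavelengths
    if wl is None:
        wl = np.arange(len(score), dtype=float)
    return WavelengthSelectionResult(
        method="pca_loadings",
        band_indices=chosen,
        wavelengths=np.asarray(wl, float)[chosen],
        scores=score,
        n_requested=n_select,
    )


def select_by_ica_weights(
    model: ICAModel,
    n_select: int = 20,
    wavelengths: np.ndarray | None = None,
) -> WavelengthSelectionResult:
    """Effective wavelengths by mean absolute FastICA unmixing weight."""
    score = np.mean(np.abs(model.unmixing), axis=0)
    chosen = _rank_and_sort(np.arange(len(score)), score, n_select)
    wl = wavelengths if wavelengths is not None else model.wavelengths
    if wl is None:
        wl = np.arange(len(score), dtype=float)
    return WavelengthSelectionResult(
        method="ica_weights",
        band_indices=chosen,
        wavelengths=np.asarray(wl, float)[chosen],
        scores=score,
        n_requested=n_select,
    )
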