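"""Spectral preprocessing: wavelet denoising, SNV scatter removal, ROI averages.

The chain mirrors standard NIR chemometrics practice: each pixel spectrum is
first smoothed by a Daubechies-7 wavelet transform at decomposition level 3,
then normalised by the standard normal variate (per-spectrum centring and
scaling to zero mean / unit SD), which removes the per-pixel multiplicative
gain and additive offset caused by light scattering.  Object-wise (mean ROI)
spectra are computed from the *preprocessed* pixel spectra, in that order.

Wavelet detail handling: the default reconstructs from the level-3
approximation with all detail coefficients zeroed — a deterministic,
parameter-free low-pass (and a linear operator).  A soft-threshold
alternative (universal threshold, noise scale from the median absolute
finest-detail coefficient) is available via ``detail="soft"``.  Signals are
extended symmetrically at the boundaries, which slightly biases the outermost
bands of a spectrum.
"""

from __future__ import annotations

import numpy as np
import pywt

from .tables import ObjectSpectraTable, PixelSpectraTable

__all__ = ["wt_smooth", "snv", "preprocess_pixels", "average_by_object"]


def wt_smooth(
    spectra: np.ndarray,
    wavelet: str = "db7",
    level: int = 3,
    detail: str = "zero",
) -> np.ndarray:
    """Wavelet-denoise one spectrum or a ``rows x bands`` matrix along bands.

    ``detail="zero"`` zeroes all detail levels (pure low-pass, linear);
    ``detail="soft"`` soft-thresholds them at the universal threshold.
    """
    x = np.asarray(spectra, dtype=float)
    n = x.shape[-1]
    wav = pywt.Wavelet(wavelet)
    if pywt.dwt_max_level(n, wav.dec_len) < level:
        raise ValueError(
            f"spectrum of length {n} is too short for a level-{level} "
            f"{wavelet} decomposition"
        )
    coeffs = pywt.wavedec(x, wav, level=level, mode="symmetric", axis=-1)
    if detail == "zero":
        coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    elif detail == "soft":
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest), axis=-1, keepdims=True) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(n))
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, "soft") for c in coeffs[1:]]
    else:
        raise ValueError(f"unknown detail mode {detail!r}")
    out = pywt.waverec(coeffs, wav, mode="symmetric", axis=-1)
    return out[..., :n]


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: per spectrum, subtract the mean and divide by
    the sample standard deviation (n-1 denominator).

    Output rows have mean 0 and sample SD 1; the transform is invariant to
    any per-spectrum positive gain and additive offset.  Zero-variance rows
    are rejected with the offending row index.
    """
    x = np.asarray(spectra, dtype=float)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    bad = np.nonzero(sd.ravel() == 0.0)[0]
    if bad.size:
        raise ValueError(
            f"SNV undefined for zero-variance spectrum at row(s) {bad.tolist()}"
        )
    return (x - mean) / sd


def preprocess_pixels(
    table: PixelSpectraTable,
    wavelet: str = "db7",
    level: int = 3,
    detail: str = "zero",
) -> PixelSpectraTable:
    """WT smoothing followed by SNV on every pixel row; labels untouched."""
    if table.stage != "raw":
        raise ValueError(f"expected a raw table, got stage {table.stage!r}")
    smoothed = wt_smooth(table.spectra, wavelet=wavelet, level=level, detail=detail)
    return table.with_stage(snv(smoothed), "wt+snv")


def average_by_object(table: PixelSpectraTable) -> ObjectSpectraTable:
    """Mean preprocessed spectrum per (scene, object) ROI."""
    if table.stage != "wt+snv":
        raise ValueError(
            f"object averages are taken after preprocessing, got stage {table.stage!r}"
        )
    meta = table.meta
    keys = list(zip(meta["scene_id"], meta["object_id"]))
    order: dict[tuple, int] = {}
    for key in keys:
        order.setdefault(key, len(order))
    idx = np.fromiter((order[k] for k in keys), dtype=int, count=len(keys))
    n_groups = len(order)
    sums = np.zeros((n_groups, table.bands))
    counts = np.zeros(n_groups, dtype=int)
    np.add.at(sums, idx, table.spectra)
    np.add.at(counts, idx, 1)
    spectra = sums / counts[:, None]

    first_rows = np.zeros(n_groups, dtype=int)
    seen = set()
    for i, key in enumerate(keys):
        if key not in seen:
            seen.add(key)
            first_rows[order[key]] = i
    import pandas as pd

    obj_meta = meta.iloc[first_rows][["scene_id", "object_id", "class", "grade"]].copy()
    obj_meta["n_pixels"] = counts
    return ObjectSpectraTable(
        spectra=spectra,
        meta=obj_meta.reset_index(drop=True),
        wavelengths=table.wavelengths,
        stage=table.stage,
    )
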