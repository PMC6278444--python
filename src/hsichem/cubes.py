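"""Hyperspectral cube container, ENVI-style I/O and image-domain operations.

A cube is a ``rows x cols x bands`` raster with an ascending wavelength axis
in nanometres.  Raw cubes hold sensor counts and are converted to relative
reflectance with white/dark reference frames::

    R = (I_raw - I_dark) / (I_white - I_dark)

Background is removed by thresholding a single near-infrared band and the
remaining foreground is split into per-object regions of interest (ROIs) by
connected-component labelling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from skimage import measure, morphology, segmentation

from .tables import PixelSpectraTable

__all__ = [
    "HyperspectralCube",
    "ReferenceFrames",
    "ObjectMask",
    "read_cube",
    "write_cube",
    "correct_reflectance",
    "nearest_band",
    "segment_background",
    "label_objects",
    "extract_pixel_spectra",
]

#: default band (nm) and reflectance threshold used for background removal
SEGMENTATION_BAND_NM = 1119.0
SEGMENTATION_THRESHOLD = 0.122

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


@dataclass
class HyperspectralCube:
    """3-D spectral raster plus its wavelength axis.

    Parameters
    ----------
    data:
        Array of shape ``(rows, cols, bands)``; raw counts or reflectance.
    wavelengths:
        Strictly increasing vector of band centres in nm, length ``bands``.
    stage:
        ``"raw"`` for sensor counts, ``"corrected"`` for reflectance.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {self.wavelengths.size} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.stage not in ("raw", "corrected"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferenceFrames:
    """White (near-100% reflectivity) and dark (shutter closed) reference frames.

    Frames may be 2-D ``(rows, cols)`` — one gain/offset per pixel shared by
    all bands, the line-scan case — or full 3-D rasters; they are broadcast
    against the cube.  White must exceed dark everywhere or the reflectance
    ratio is undefined.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")
        if not np.all(self.white > self.dark):
            raise ValueError("white frame must exceed dark frame elementwise")

    def broadcast(self, cube_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        w, d = self.white, self.dark
        if w.ndim == 2:
            w = w[:, :, None]
            d = d[:, :, None]
        np.broadcast_shapes(w.shape, cube_shape)
        return w, d


@dataclass
class ObjectMask:
    """Foreground mask plus per-object integer labels (0 = background)."""

    mask: np.ndarray
    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        if self.mask.shape != self.labels.shape:
            raise ValueError("mask and labels must share a shape")
        present = np.unique(self.labels[self.labels > 0])
        if len(present) != self.n_objects or (
            self.n_objects and present[-1] != self.n_objects
        ):
            raise ValueError("labels must be 1..n_objects with no gaps")
        if not np.array_equal(self.labels > 0, self.mask.astype(bool)):
            raise ValueError("labels must be nonzero exactly on the mask support")


# ---------------------------------------------------------------------------
# ENVI-style I/O


def _format_envi_header(cube: HyperspectralCube, interleave: str) -> str:
    rows, cols, bands = cube.shape
    code = _ENVI_CODES[np.dtype(cube.data.dtype)]
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    return (
        "ENVI\n"
        "description = {hsichem cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"stage = {cube.stage}\n"
        "wavelength = {" + wl + "}\n"
    )


def _parse_envi_header(text: str) -> dict:
    # collapse brace-delimited values that may span lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def write_cube(
    cube: HyperspectralCube,
    path: str | Path,
    dialect: str = "envi",
    interleave: str = "bsq",
) -> Path:
    """Write a cube either as an ENVI header/raster pair or as an ``.npz``.

    For ``dialect="envi"`` the path is the raster file; ``<path>.hdr`` is
    written next to it.  Interleaves ``bsq`` (band-sequential) and ``bil``
    (band-interleaved-by-line) are supported.
    """
    path = Path(path)
    if dialect == "internal":
        np.savez(
            path,
            data=cube.data,
            wavelengths=cube.wavelengths,
            stage=np.array(cube.stage),
        )
        return path
    if dialect != "envi":
        raise ValueError(f"unknown dialect {dialect!r}")
    interleave = interleave.lower()
    if interleave == "bsq":
        arr = np.transpose(cube.data, (2, 0, 1))
    elif interleave == "bil":
        arr = np.transpose(cube.data, (0, 2, 1))
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    if np.dtype(cube.data.dtype) not in _ENVI_CODES:
        arr = arr.astype(np.float64)
        cube = HyperspectralCube(cube.data.astype(np.float64), cube.wavelengths, cube.stage)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(path.suffix + ".hdr").write_text(
        _format_envi_header(cube, interleave)
    )
    arr.astype(cube.data.dtype).tofile(path)
    return path


def read_cube(path: str | Path, dialect: str = "envi") -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`.

    Raises if wavelength metadata is missing or the header geometry does not
    match the raster size.
    """
    path = Path(path)
    if dialect == "internal":
        with np.load(path) as npz:
            return HyperspectralCube(
                npz["data"], npz["wavelengths"], str(npz["stage"])
            )
    if dialect != "envi":
        raise ValueError(f"unknown dialect {dialect!r}")
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header {hdr_path} missing field {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError(f"ENVI header {hdr_path} has no wavelength metadata")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array(
        [float(tok) for tok in wl_text.split(",") if tok.strip()], dtype=float
    )
    if len(wavelengths) != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )
    raw = np.fromfile(path, dtype=_ENVI_DTYPES[code])
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"raster size {raw.size} does not match header geometry "
            f"{rows}x{cols}x{bands}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return HyperspectralCube(data, wavelengths, fields.get("stage", "raw"))


# ---------------------------------------------------------------------------
# Image-domain operations


def correct_reflectance(
    raw: HyperspectralCube, refs: ReferenceFrames
) -> HyperspectralCube:
    """Convert raw counts to relative reflectance.

    Applies ``(I_raw - I_dark) / (I_white - I_dark)`` elementwise, the
    standard white/dark calibration of push-broom NIR imagers.
    """
    if raw.stage != "raw":
        raise ValueError(f"expected a raw cube, got stage {raw.stage!r}")
    white, dark = refs.broadcast(raw.shape)
    corrected = (raw.data - dark) / (white - dark)
    return HyperspectralCube(corrected, raw.wavelengths, stage="corrected")


def nearest_band(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the band closest to ``target_nm``; ties go to the lower wavelength."""
    return int(np.argmin(np.abs(np.asarray(wavelengths) - target_nm)))


def segment_background(
    cube: HyperspectralCube,
    band_nm: float = SEGMENTATION_BAND_NM,
    threshold: float = SEGMENTATION_THRESHOLD,
) -> np.ndarray:
    """Foreground mask: reflectance at the band nearest ``band_nm`` strictly above
    ``threshold``.  A pixel exactly at the threshold counts as background."""
    if cube.stage != "corrected":
        raise ValueError("segmentation expects a reflectance-corrected cube")
    wl = cube.wavelengths
    if not (wl[0] <= band_nm <= wl[-1]):
        raise ValueError(
            f"segmentation band {band_nm} nm outside axis [{wl[0]}, {wl[-1]}] nm"
        )
    b = nearest_band(wl, band_nm)
    return cube.data[:, :, b] > threshold


def label_objects(
    mask: np.ndarray, min_size: int = 5, connectivity: int = 2
) -> ObjectMask:
    """Split a foreground mask into ROIs by 8-connected component labelling.

    Components below ``min_size`` pixels are discarded as salt noise and the
    surviving labels renumbered 1..n.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype == object:
        raise ValueError("mask must be a 2-D boolean raster")
    mask = mask.astype(bool)
    if min_size > 1:
        # max_size semantics: removes components of at most that many pixels
        mask = morphology.remove_small_objects(
            mask, max_size=min_size - 1, connectivity=connectivity
        )
    labels = measure.label(mask, connectivity=connectivity)
    relabelled, _, _ = segmentation.relabel_sequential(labels)
    n = int(relabelled.max())
    return ObjectMask(mask=relabelled > 0, labels=relabelled, n_objects=n)


def extract_pixel_spectra(
    cube: HyperspectralCube,
    objmask: ObjectMask,
    scene_id: str = "scene",
    class_by_object: Mapping[int, str] | str | None = None,
    grade: str | None = None,
) -> PixelSpectraTable:
    """One table row per ROI pixel: the pixel's spectrum plus scene/object/
    class/grade labels and its (row, col) coordinate.

    ``class_by_object`` is either a single class for the whole scene or a
    mapping from object id to class.
    """
    if cube.stage != "corrected":
        raise ValueError("pixel extraction expects a reflectance-corrected cube")
    if objmask.labels.shape != cube.shape[:2]:
        raise ValueError("object mask is not aligned with the cube")
    spectra, meta_rows = [], []
    for obj in range(1, objmask.n_objects + 1):
        rr, cc = np.nonzero(objmask.labels == obj)
        spectra.append(cube.data[rr, cc, :])
        if isinstance(class_by_object, Mapping):
            cls = class_by_object.get(obj)
        else:
            cls = class_by_object
        for r, c in zip(rr, cc):
            meta_rows.append((scene_id, obj, cls, grade, int(r), int(c)))
    import pandas as pd

    meta = pd.DataFrame(
        meta_rows, columns=["scene_id", "object_id", "class", "grade", "row", "col"]
    )
    if spectra:
        mat = np.vstack(spectra)
    else:
        mat = np.empty((0, cube.bands))
    return PixelSpectraTable(
        spectra=mat, meta=meta, wavelengths=cube.wavelengths, stage="raw"
    )
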