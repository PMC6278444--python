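"""Tabular containers for pixel-wise and object-wise spectra.

Both tables pair a dense ``rows x bands`` spectra matrix with a pandas
metadata frame carrying scene/object/class/grade labels, so downstream
stages (preprocessing, wavelength selection, classification) can slice by
label without losing track of provenance.  ``stage`` records how far a table
has moved along the preprocessing chain and may only advance:
``raw -> wt -> wt+snv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["PixelSpectraTable", "ObjectSpectraTable", "STAGES"]

STAGES = ("raw", "wt", "wt+snv")

_PIXEL_META = ["scene_id", "object_id", "class", "grade", "row", "col"]
_OBJECT_META = ["scene_id", "object_id", "class", "grade", "n_pixels"]


def _check(spectra: np.ndarray, meta: pd.DataFrame, wavelengths: np.ndarray, stage: str):
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("spectra must be a 2-D rows x bands matrix")
    if len(meta) != spectra.shape[0]:
        raise ValueError(
            f"metadata has {len(meta)} rows but spectra matrix has {spectra.shape[0]}"
        )
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != spectra.shape[1]:
        raise ValueError("wavelength axis does not match spectra width")
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if np.isnan(spectra).any():
        raise ValueError("spectra contain missing values")
    return spectra, wavelengths


@dataclass
class PixelSpectraTable:
    """Per-pixel spectra with scene/object/class/grade labels."""

    spectra: np.ndarray
    meta: pd.DataFrame
    wavelengths: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.spectra, self.wavelengths = _check(
            self.spectra, self.meta, self.wavelengths, self.stage
        )
        missing = [c for c in _PIXEL_META if c not in self.meta.columns]
        if missing:
            raise ValueError(f"pixel metadata missing columns {missing}")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def bands(self) -> int:
        return self.spectra.shape[1]

    def with_stage(self, spectra: np.ndarray, stage: str) -> "PixelSpectraTable":
        """New table with replaced spectra at an advanced stage; labels untouched."""
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValueError(f"stage may only advance (have {self.stage!r}, got {stage!r})")
        return PixelSpectraTable(spectra, self.meta.copy(), self.wavelengths, stage)

    def select_rows(self, index: Sequence[int] | np.ndarray) -> "PixelSpectraTable":
        index = np.asarray(index)
        out = PixelSpectraTable.__new__(PixelSpectraTable)
        out.spectra = self.spectra[index]
        out.meta = self.meta.iloc[index].reset_index(drop=True)
        out.wavelengths = self.wavelengths
        out.stage = self.stage
        return out

    @staticmethod
    def concat(tables: Iterable["PixelSpectraTable"]) -> "PixelSpectraTable":
        tables = list(tables)
        if not tables:
            raise ValueError("nothing to concatenate")
        stages = {t.stage for t in tables}
        if len(stages) != 1:
            raise ValueError(f"cannot concatenate mixed stages {stages}")
        wl = tables[0].wavelengths
        for t in tables[1:]:
            if not np.array_equal(t.wavelengths, wl):
                raise ValueError("wavelength axes differ between tables")
        return PixelSpectraTable(
            np.vstack([t.spectra for t in tables]),
            pd.concat([t.meta for t in tables], ignore_index=True),
            wl,
            tables[0].stage,
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.meta.copy()
        bands = pd.DataFrame(
            self.spectra, columns=[f"band_{i}" for i in range(self.bands)]
        )
        pd.concat([df, bands], axis=1).to_csv(path, index=False)
        return path

    @staticmethod
    def from_csv(
        path: str | Path, wavelengths: np.ndarray, stage: str = "raw"
    ) -> "PixelSpectraTable":
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c.startswith("band_")]
        return PixelSpectraTable(
            df[band_cols].to_numpy(float), df[_PIXEL_META], wavelengths, stage
        )


@dataclass
class ObjectSpectraTable:
    """One mean spectrum per ROI; each row averages its object's pixel rows."""

    spectra: np.ndarray
    meta: pd.DataFrame
    wavelengths: np.ndarray
    stage: str = "wt+snv"

    def __post_init__(self) -> None:
        self.spectra, self.wavelengths = _check(
            self.spectra, self.meta, self.wavelengths, self.stage
        )
        missing = [c for c in _OBJECT_META if c not in self.meta.columns]
        if missing:
            raise ValueError(f"object metadata missing columns {missing}")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def bands(self) -> int:
        return self.spectra.shape[1]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        bands = pd.DataFrame(
            self.spectra, columns=[f"band_{i}" for i in range(self.bands)]
        )
        pd.concat([self.meta.copy(), bands], axis=1).to_csv(path, index=False)
        return path
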