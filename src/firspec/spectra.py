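"""The samples x bands reflectance container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .grid import WavelengthGrid

#: number formatting for band column headers in CSV exports
_BAND_FMT = "{:.4f}"


@dataclass
class SpectraSet:
    """Reflectance matrix (samples x bands) with ids, group labels and trait truth.

    ``truth`` is an optional DataFrame indexed like ``ids`` with columns
    ``group``, ``lcc`` (mg/g) and ``lwc`` (fraction).
    """

    grid: WavelengthGrid
    matrix: np.ndarray
    ids: list[str]
    truth: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise InvalidConfigError("spectra matrix must be 2-D (samples x bands)")
        if self.matrix.shape[1] != self.grid.n_bands:
            raise InvalidConfigError(
                f"matrix has {self.matrix.shape[1]} bands but grid has {self.grid.n_bands}"
            )
        if len(self.ids) != self.matrix.shape[0]:
            raise InvalidConfigError("one id per spectrum required")
        if len(set(self.ids)) != len(self.ids):
            raise InvalidConfigError("sample ids must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidConfigError("reflectance values must be finite")
        if self.truth is not None:
            self.truth = self.truth.loc[self.ids]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def target(self, name: str) -> np.ndarray:
        """Trait vector (``lcc`` or ``lwc``) aligned with the matrix rows."""
        if self.truth is None:
            raise InvalidConfigError("spectra set carries no trait truth")
        return self.truth[name].to_numpy(dtype=float)

    @property
    def groups(self) -> np.ndarray:
        if self.truth is None:
            raise InvalidConfigError("spectra set carries no group labels")
        return self.truth["group"].to_numpy()

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        """Row subset (e.g. a calibration or prediction split), order preserved."""
        pos = {s: i for i, s in enumerate(self.ids)}
        rows = [pos[s] for s in ids]
        truth = self.truth.loc[list(ids)] if self.truth is not None else None
        return SpectraSet(self.grid, self.matrix[rows], list(ids), truth)

    def with_matrix(self, matrix: np.ndarray) -> "SpectraSet":
        """Same samples/metadata with a transformed matrix (used by preprocessing)."""
        return SpectraSet(self.grid, matrix, list(self.ids), self.truth)

    # ------------------------------------------------------------------ CSV
    def to_csv(self, path: str | Path) -> None:
        """Write ``sample_id, group, lcc, lwc, <band columns in nm>``."""
        df = pd.DataFrame(
            self.matrix,
            index=pd.Index(self.ids, name="sample_id"),
            columns=[_BAND_FMT.format(w) for w in self.grid.wavelengths_nm],
        )
        if self.truth is not None:
            meta = self.truth[["group", "lcc", "lwc"]]
            df = pd.concat([meta, df], axis=1)
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraSet":
        df = pd.read_csv(path, index_col="sample_id")
        meta_cols = [c for c in ("group", "lcc", "lwc") if c in df.columns]
        band_cols = [c for c in df.columns if c not in meta_cols]
        grid = WavelengthGrid(np.array([float(c) for c in band_cols]))
        truth = df[meta_cols] if meta_cols else None
        ids = [str(i) for i in df.index]
        if truth is not None:
            truth = truth.set_axis(ids, axis=0)
        return cls(grid, df[band_cols].to_numpy(dtype=float), ids, truth)
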