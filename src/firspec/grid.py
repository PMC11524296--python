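"""Wavelength grid shared by cubes, spectra and selection results.

The default grid matches the push-broom NIR imager the synthetic generator
emulates: 512 bands spanning 870-1720 nm inclusive, uniformly spaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError

DEFAULT_N_BANDS = 512
DEFAULT_RANGE_NM = (870.0, 1720.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nanometres.

    Invariant: strictly increasing.  Equality is value-based so grids read
    back from an ENVI header compare equal to the grid they were written from.
    """

    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.linspace(*DEFAULT_RANGE_NM, DEFAULT_N_BANDS)
    )

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise InvalidConfigError("wavelength grid must be a 1-D array with >= 2 bands")
        if not np.all(np.diff(wl) > 0):
            raise InvalidConfigError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths_nm.size)

    def index_of_nearest(self, nm: float) -> int:
        """Index of the band center closest to ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - nm)))

    def contains(self, nm: float) -> bool:
        return bool(self.wavelengths_nm[0] <= nm <= self.wavelengths_nm[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.n_bands == other.n_bands
            and bool(np.allclose(self.wavelengths_nm, other.wavelengths_nm))
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.n_bands, float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])))
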