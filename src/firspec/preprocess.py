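"""Spectral preprocessing: Savitzky-Golay smoothing, SNV and MSC.

All three transforms are row-wise: no information flows between samples,
except MSC's reference spectrum, which must be estimated on the calibration
set only and frozen before touching prediction data (the
:class:`Preprocessor` enforces this fit/transform discipline).

Conventions worth naming because they change numbers:

* SG edges use polynomial extrapolation on the truncated window
  (``mode="interp"``), so no padding artifacts; the derivative step is per
  band index.
* SNV divides by the population standard deviation (ddof=0).
* MSC regresses each spectrum on the reference by ordinary least squares,
  x ~ a*r + b, and returns (x - b)/a.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSpectrumError, InvalidConfigError
from .spectra import SpectraSet

_METHODS = ("none", "sg", "snv", "msc")


@dataclass(frozen=True)
class PreprocessSpec:
    method: str = "sg"
    sg_window: int = 11
    sg_polyorder: int = 2
    sg_deriv: int = 0
    msc_reference: Optional[np.ndarray] = None  # default: mean of the fitted set

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise InvalidConfigError(f"method must be one of {_METHODS}")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise InvalidConfigError("sg_window must be an odd integer >= 3")
        if not (0 <= self.sg_polyorder < self.sg_window):
            raise InvalidConfigError("sg_polyorder must satisfy 0 <= order < window")
        if not (0 <= self.sg_deriv <= self.sg_polyorder):
            raise InvalidConfigError("sg_deriv must satisfy 0 <= deriv <= polyorder")


def sg_smooth(spectra: SpectraSet, spec: PreprocessSpec = PreprocessSpec()) -> SpectraSet:
    """Savitzky-Golay filter along the band axis (window/order/deriv from spec)."""
    if spec.sg_window > spectra.grid.n_bands:
        raise InvalidConfigError(
            f"sg_window={spec.sg_window} exceeds band count {spectra.grid.n_bands}"
        )
    out = savgol_filter(
        spectra.matrix, window_length=spec.sg_window, polyorder=spec.sg_polyorder,
        deriv=spec.sg_deriv, delta=1.0, axis=1, mode="interp",
    )
    return spectra.with_matrix(out)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-spectrum centering and unit (population) sd."""
    x = spectra.matrix
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        bad = [spectra.ids[i] for i in flat]
        raise DegenerateSpectrumError(f"zero-variance spectra cannot be SNV-scaled: {bad}")
    return spectra.with_matrix((x - mu) / sd)


def msc(
    spectra: SpectraSet,
    reference: Optional[np.ndarray] = None,
) -> tuple[SpectraSet, np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against ``reference`` (default: set mean).

    Returns the corrected set plus the fitted per-sample (gain, offset)
    arrays.  Pass the calibration-set reference explicitly when correcting
    prediction data.
    """
    x = spectra.matrix
    r = x.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if r.shape != (x.shape[1],):
        raise InvalidConfigError("MSC reference length must equal the band count")
    r_c = r - r.mean()
    denom = float(r_c @ r_c)
    if denom == 0:
        raise DegenerateSpectrumError("MSC reference has zero variance")
    # OLS of each row on (r, 1): slope via centered covariance
    a = (x - x.mean(axis=1, keepdims=True)) @ r_c / denom
    tiny = np.abs(a) < 1e-12
    if tiny.any():
        bad = [spectra.ids[i] for i in np.flatnonzero(tiny)]
        raise DegenerateSpectrumError(f"MSC gain ~ 0 for samples {bad}")
    b = x.mean(axis=1) - a * r.mean()
    corrected = (x - b[:, None]) / a[:, None]
    return spectra.with_matrix(corrected), a, b


class Preprocessor:
    """Fit/transform wrapper that freezes any data-dependent state.

    Only MSC has state (the reference spectrum); SG and SNV are stateless but
    go through the same interface so pipeline code cannot leak by accident.
    """

    def __init__(self, spec: PreprocessSpec):
        self.spec = spec
        self.msc_reference_: Optional[np.ndarray] = None

    def fit(self, calibration: SpectraSet) -> "Preprocessor":
        if self.spec.method == "msc":
            if self.spec.msc_reference is not None:
                self.msc_reference_ = np.asarray(self.spec.msc_reference, dtype=float)
            else:
                self.msc_reference_ = calibration.matrix.mean(axis=0)
        return self

    def transform(self, spectra: SpectraSet) -> SpectraSet:
        m = self.spec.method
        if m == "none":
            return spectra
        if m == "sg":
            return sg_smooth(spectra, self.spec)
        if m == "snv":
            return snv(spectra)
        if self.msc_reference_ is None:
            raise InvalidConfigError("MSC preprocessor must be fit on calibration data first")
        corrected, _, _ = msc(spectra, reference=self.msc_reference_)
        return corrected

    def fit_transform(self, calibration: SpectraSet) -> SpectraSet:
        return self.fit(calibration).transform(calibration)
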