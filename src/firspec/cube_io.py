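"""Hyperspectral cube I/O, reflectance calibration, canopy masking and ROI extraction.

Cubes are stored in the ENVI convention: a small text header (dimensions,
interleave, data type, wavelength list) next to a raw binary payload.  In
memory a cube is always (lines, samples, bands), i.e. BIP-ordered, whatever
the on-disk interleave was.

Reflectance calibration follows the standard white/dark normalisation

    R = (I - D) / (W - D)

where I is the raw image, W the white-panel reference and D the dark-current
reference.  The canopy region of interest is a brightness mask (default: mean
reflectance over bands >= 0.45, boundary inclusive) and the per-seedling
spectrum is the arithmetic mean over masked pixels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import (
    EmptyROIError,
    EnviParseError,
    EnviSizeMismatchError,
    InvalidConfigError,
    MissingWavelengthError,
    ReferenceDegeneracyError,
    UnknownInterleaveError,
)
from .grid import WavelengthGrid

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

DEFAULT_MASK_THRESHOLD = 0.45


@dataclass
class Hypercube:
    """(lines, samples, bands) intensity or reflectance stack."""

    data: np.ndarray
    grid: WavelengthGrid
    interleave: str = "bsq"
    is_reflectance: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidConfigError("cube data must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != self.grid.n_bands:
            raise InvalidConfigError(
                f"cube has {self.data.shape[2]} bands but grid has {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(np.asarray(self.data, dtype=float))):
            raise InvalidConfigError("cube values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferenceFrames:
    """White and dark reference images.

    Either full cubes shaped like the raw image (per-pixel, per-band
    references) or scan-line references shaped (samples, bands), which are
    broadcast along the scan axis — both dialects occur in push-broom practice.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise InvalidConfigError("white and dark frames must share a shape")
        if self.white.ndim not in (2, 3):
            raise InvalidConfigError("reference frames must be (samples, bands) or full cubes")


@dataclass
class Mask:
    """Boolean canopy mask with the rule that produced it."""

    values: np.ndarray
    threshold: float
    statistic: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise InvalidConfigError("mask must be 2-D")

    @property
    def is_empty(self) -> bool:
        return not bool(self.values.any())

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


@dataclass
class Spectrum:
    """A single mean ROI spectrum."""

    grid: WavelengthGrid
    values: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bands,):
            raise InvalidConfigError("spectrum length must equal grid band count")
        if self.n_pixels < 1:
            raise InvalidConfigError("a spectrum summarises at least one pixel")


# --------------------------------------------------------------------- ENVI
def _parse_header(text: str) -> dict:
    """Parse `key = value` pairs; `{...}` lists may span lines."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise EnviParseError("not an ENVI header (missing ENVI magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    for m in re.finditer(r"([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)", body, re.DOTALL):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _data_path_for(header_path: Path) -> Path:
    for suffix in (".img", ".raw", ".dat", ""):
        candidate = header_path.with_suffix(suffix)
        if candidate.exists() and candidate != header_path:
            return candidate
    raise EnviParseError(f"no binary data file found next to {header_path}")


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI cube (BSQ or BIL) into (lines, samples, bands) order."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviParseError(f"header missing required field: {exc}") from exc
    if interleave not in ("bsq", "bil"):
        raise UnknownInterleaveError(f"unsupported interleave {interleave!r} (bsq/bil only)")
    if dtype_code not in _ENVI_DTYPES:
        raise EnviParseError(f"unsupported data type code {dtype_code}")
    if "wavelength" not in fields:
        raise MissingWavelengthError("header has no wavelength list")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise MissingWavelengthError("wavelength list must be brace-delimited")
    wavelengths = np.array(
        [float(tok) for tok in wl_text[1:-1].replace("\n", " ").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise MissingWavelengthError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    raw = np.fromfile(_data_path_for(header_path), dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviSizeMismatchError(
            f"binary holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":  # (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:  # bil: (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    return Hypercube(np.ascontiguousarray(data), WavelengthGrid(wavelengths), interleave)


def write_envi(cube: Hypercube, header_path: str | Path) -> Path:
    """Write cube as `<stem>.hdr` + `<stem>.img`; returns the header path."""
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    data_path = header_path.with_suffix(".img")
    lines, samples, bands = cube.data.shape
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _ENVI_CODES:
        raise EnviParseError(f"cannot encode dtype {dtype} in an ENVI header")
    if cube.interleave not in ("bsq", "bil"):
        raise UnknownInterleaveError(f"unsupported interleave {cube.interleave!r}")
    wl = ", ".join(f"{w:.4f}" for w in cube.grid.wavelengths_nm)
    header_path.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        f"interleave = {cube.interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    if cube.interleave == "bsq":
        out = cube.data.transpose(2, 0, 1)
    else:
        out = cube.data.transpose(0, 2, 1)
    np.ascontiguousarray(out).tofile(data_path)
    return header_path


# -------------------------------------------------------------- calibration
def calibrate_reflectance(raw: Hypercube, refs: ReferenceFrames) -> Hypercube:
    """R = (I - D) / (W - D), elementwise.

    Scan-line references (samples, bands) are broadcast over the line axis.
    Raises :class:`ReferenceDegeneracyError` naming the first location where
    W == D among the pixels/bands actually used.
    """
    I = np.asarray(raw.data, dtype=float)
    white, dark = refs.white, refs.dark
    if white.ndim == 2:
        if white.shape != I.shape[1:]:
            raise InvalidConfigError("scan-line references must be (samples, bands)")
        white = white[np.newaxis, :, :]
        dark = dark[np.newaxis, :, :]
    elif white.shape != I.shape:
        raise InvalidConfigError("full-frame references must match the cube shape")
    denom = white - dark
    bad = np.argwhere(denom == 0)
    if bad.size:
        loc = tuple(int(v) for v in bad[0])
        raise ReferenceDegeneracyError(
            f"white equals dark at (line, sample, band)={loc}; reflectance undefined"
        )
    R = (I - np.broadcast_to(dark, I.shape)) / np.broadcast_to(denom, I.shape)
    return Hypercube(R, raw.grid, raw.interleave, is_reflectance=True)


def make_mask(
    cube: Hypercube,
    threshold: float = DEFAULT_MASK_THRESHOLD,
    statistic: str = "mean",
    band_nm: Optional[float] = None,
) -> Mask:
    """Canopy mask: pixel kept iff its brightness statistic >= threshold.

    ``statistic`` is ``"mean"`` (mean reflectance over all bands) or
    ``"band"`` (reflectance at the band nearest ``band_nm``).  An empty mask
    is allowed and flagged via :attr:`Mask.is_empty`.
    """
    if not cube.is_reflectance:
        raise InvalidConfigError("mask is defined on a calibrated reflectance cube")
    if statistic == "mean":
        score = np.asarray(cube.data, dtype=float).mean(axis=2)
        tag = "mean"
    elif statistic == "band":
        if band_nm is None:
            raise InvalidConfigError("statistic='band' requires band_nm")
        score = np.asarray(cube.data, dtype=float)[:, :, cube.grid.index_of_nearest(band_nm)]
        tag = f"band@{band_nm:g}nm"
    else:
        raise InvalidConfigError(f"unknown mask statistic {statistic!r}")
    return Mask(score >= threshold, threshold, tag)


def extract_roi_mean(cube: Hypercube, mask: Mask) -> Spectrum:
    """Per-band arithmetic mean over masked pixels."""
    if mask.values.shape != cube.data.shape[:2]:
        raise InvalidConfigError("mask shape must match cube spatial dimensions")
    if mask.is_empty:
        raise EmptyROIError("mask selects no pixels; cannot form a mean spectrum")
    pixels = np.asarray(cube.data, dtype=float)[mask.values]
    return Spectrum(cube.grid, pixels.mean(axis=0), n_pixels=pixels.shape[0])
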