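"""Synthetic drought-gradient dataset generator.

Emulates the study design the pipeline was built for: 180 conifer seedlings in
five drought groups (D0, D14, D28, D42, D56; 36 seedlings each) whose needle
chlorophyll content (LCC, mg/g) and water content (LWC, fraction) decline with
drought duration, imaged on a 512-band 870-1720 nm NIR grid.

The generative model for a spectrum is deliberately minimal:

    x(l) = g * [ b(l) - sum_f depth_f * exp(-((l - c_f)^2) / (2 w_f^2)) ] + o + e(l)

with a gentle quadratic baseline continuum b(l), Gaussian absorption features
at the water overtone bands (970, 1450 nm; depth proportional to LWC) and the
chlorophyll-linked N-H/C-H bands (1100, 1190 nm; depth proportional to LCC),
a per-sample affine scatter distortion (gain g, offset o) and additive
Gaussian noise e.  It reproduces the qualitative features real canopy spectra
show on this grid — and gives MSC/SNV genuine scatter to remove — without
attempting radiative-transfer realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cube_io import Hypercube, Mask, ReferenceFrames
from .errors import InvalidConfigError
from .grid import WavelengthGrid
from .spectra import SpectraSet

GROUPS = ("D0", "D14", "D28", "D42", "D56")

#: group-mean traits along the drought gradient (D0 ... D56)
DEFAULT_LCC_MEANS = (2.4, 1.8, 1.2, 0.6, 0.1)   # mg/g
DEFAULT_LWC_MEANS = (0.68, 0.55, 0.40, 0.25, 0.09)  # fraction


@dataclass(frozen=True)
class TraitTruth:
    """Ground-truth traits of one seedling."""

    sample_id: str
    group: str
    lcc: float  # mg chlorophyll per g fresh needles, >= 0
    lwc: float  # water fraction of fresh weight, in [0, 1]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidConfigError(f"unknown group {self.group!r}")
        if self.lcc < 0 or not (0.0 <= self.lwc <= 1.0):
            raise InvalidConfigError("traits outside physical bounds")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_per_group: int = 36
    seed: int = 0
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    lcc_group_means: Sequence[float] = DEFAULT_LCC_MEANS
    lwc_group_means: Sequence[float] = DEFAULT_LWC_MEANS
    trait_sd_frac: float = 0.10          # within-group sd as fraction of the group mean
    noise_sd: float = 0.002              # additive reflectance noise
    scatter_gain_sd: float = 0.05        # multiplicative scatter, sd of gain around 1
    scatter_offset_sd: float = 0.01      # additive scatter offset sd
    feature_centers_nm: Sequence[float] = (970.0, 1100.0, 1190.0, 1450.0)
    feature_widths_nm: Sequence[float] = (45.0, 35.0, 40.0, 60.0)
    feature_traits: Sequence[str] = ("lwc", "lcc", "lcc", "lwc")
    feature_gains: Sequence[float] = (0.25, 0.08, 0.06, 0.55)  # depth per trait unit
    baseline_coeffs: Sequence[float] = (0.85, -0.08, -0.05)    # b0 + b1*u + b2*u^2

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise InvalidConfigError("n_per_group must be positive")
        if min(self.noise_sd, self.scatter_gain_sd, self.scatter_offset_sd,
               self.trait_sd_frac) < 0:
            raise InvalidConfigError("all standard deviations must be >= 0")
        n_feat = len(self.feature_centers_nm)
        if not (len(self.feature_widths_nm) == len(self.feature_traits)
                == len(self.feature_gains) == n_feat):
            raise InvalidConfigError("feature_* sequences must have equal length")
        for c in self.feature_centers_nm:
            if not self.grid.contains(c):
                raise InvalidConfigError(f"feature center {c} nm outside the grid range")
        if any(t not in ("lcc", "lwc") for t in self.feature_traits):
            raise InvalidConfigError("feature_traits entries must be 'lcc' or 'lwc'")

    @property
    def n_samples(self) -> int:
        return 5 * self.n_per_group


def _streams(seed: int, n: int = 3) -> list[np.random.Generator]:
    """Independent child generators so traits/spectra/cubes draw separately."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_traits(config: SyntheticConfig) -> list[TraitTruth]:
    """Draw per-seedling traits around the drought-group means.

    Draws are normal with sd = ``trait_sd_frac`` x group mean, truncated at the
    physical bounds (lcc >= 0, lwc in [0, 1]) by resampling.  Deterministic
    under a fixed seed.
    """
    rng = _streams(config.seed)[0]

    def truncated(mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
        out = rng.normal(mean, sd, size)
        for _ in range(1000):
            bad = (out < lo) | (out > hi)
            if not bad.any():
                return out
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
        return np.clip(out, lo, hi)  # pathological sds only

    truths: list[TraitTruth] = []
    for gi, group in enumerate(GROUPS):
        lcc_mu = float(config.lcc_group_means[gi])
        lwc_mu = float(config.lwc_group_means[gi])
        lcc = truncated(lcc_mu, config.trait_sd_frac * lcc_mu, 0.0, np.inf, config.n_per_group)
        lwc = truncated(lwc_mu, config.trait_sd_frac * lwc_mu, 0.0, 1.0, config.n_per_group)
        for j in range(config.n_per_group):
            truths.append(
                TraitTruth(f"{group}-{j + 1:02d}", group, float(lcc[j]), float(lwc[j]))
            )
    return truths


def clean_spectrum(truth: TraitTruth, config: SyntheticConfig) -> np.ndarray:
    """Noise- and scatter-free spectrum for one trait pair (the generative mean)."""
    wl = config.grid.wavelengths_nm
    span = wl[-1] - wl[0]
    u = (wl - 0.5 * (wl[0] + wl[-1])) / span  # in [-0.5, 0.5]
    b0, b1, b2 = config.baseline_coeffs
    x = b0 + b1 * u + b2 * u * u
    traits = {"lcc": truth.lcc, "lwc": truth.lwc}
    for c, w, t, g in zip(config.feature_centers_nm, config.feature_widths_nm,
                          config.feature_traits, config.feature_gains):
        x = x - g * traits[t] * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return x


def simulate_spectra(truths: Sequence[TraitTruth], config: SyntheticConfig) -> SpectraSet:
    """Generate the reflectance matrix for a list of trait truths.

    Scatter is an affine per-sample distortion (gain ~ N(1, scatter_gain_sd),
    offset ~ N(0, scatter_offset_sd)); small per-sample slope/curvature jitter
    of the baseline is tied to ``scatter_offset_sd`` so that a zero-scatter,
    zero-noise configuration is a deterministic map of the traits.  Output is
    clipped to (0, 1.2].
    """
    rng = _streams(config.seed)[1]
    wl = config.grid.wavelengths_nm
    span = wl[-1] - wl[0]
    u = (wl - 0.5 * (wl[0] + wl[-1])) / span
    n = len(truths)
    base = np.vstack([clean_spectrum(t, config) for t in truths])

    slope_jit = rng.normal(0.0, config.scatter_offset_sd, n)
    curv_jit = rng.normal(0.0, config.scatter_offset_sd, n)
    gain = rng.normal(1.0, config.scatter_gain_sd, n)
    offset = rng.normal(0.0, config.scatter_offset_sd, n)
    noise = rng.normal(0.0, config.noise_sd, (n, wl.size)) if config.noise_sd > 0 else 0.0

    matrix = base + slope_jit[:, None] * u[None, :] + curv_jit[:, None] * (u * u)[None, :]
    matrix = gain[:, None] * matrix + offset[:, None] + noise
    matrix = np.clip(matrix, 1e-6, 1.2)

    ids = [t.sample_id for t in truths]
    truth = pd.DataFrame(
        {"group": [t.group for t in truths],
         "lcc": [t.lcc for t in truths],
         "lwc": [t.lwc for t in truths]},
        index=ids,
    )
    return SpectraSet(config.grid, matrix, ids, truth)


def simulate_dataset(config: SyntheticConfig) -> SpectraSet:
    """Convenience: traits then spectra under one config/seed."""
    return simulate_spectra(simulate_traits(config), config)


# ------------------------------------------------------------------- cubes
#: digital-number scale of the emulated sensor
_WHITE_LEVEL = 4000.0
_DARK_LEVEL = 100.0
_BACKGROUND_REFLECTANCE = 0.05


def simulate_cube(
    truth_row: TraitTruth,
    config: SyntheticConfig,
    scene_shape: tuple[int, int] = (24, 24),
) -> tuple[Hypercube, ReferenceFrames, Mask]:
    """Raw-intensity scene for one seedling, with references and the true mask.

    Canopy pixels (a centred disk) carry the sample's clean spectrum plus
    per-pixel noise; background pixels sit at a low flat reflectance.  The
    white frame is near full scale with a smooth spatial illumination pattern,
    the dark frame near the sensor offset, so calibration has real work to do.
    """
    lines, samples = scene_shape
    if lines < 2 or samples < 2:
        raise InvalidConfigError("scene must be at least 2x2 pixels")
    rng = _streams(config.seed)[2]
    nb = config.grid.n_bands

    yy, xx = np.mgrid[0:lines, 0:samples]
    cy, cx = (lines - 1) / 2.0, (samples - 1) / 2.0
    radius = 0.35 * min(lines, samples)
    true_mask = ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius**2

    spectrum = clean_spectrum(truth_row, config)
    R = np.full((lines, samples, nb), _BACKGROUND_REFLECTANCE)
    R[true_mask] = spectrum[None, :]
    if config.noise_sd > 0:
        R[true_mask] += rng.normal(0.0, config.noise_sd, (int(true_mask.sum()), nb))

    # smooth illumination falloff toward scene edges, same for W and the scene
    illum = 1.0 - 0.05 * (((yy - cy) / max(cy, 1)) ** 2 + ((xx - cx) / max(cx, 1)) ** 2)
    white = _WHITE_LEVEL * illum[:, :, None] * np.ones((1, 1, nb))
    dark = np.full((lines, samples, nb), _DARK_LEVEL)
    raw = dark + R * (white - dark)

    cube = Hypercube(raw, config.grid, interleave="bsq", is_reflectance=False)
    refs = ReferenceFrames(white=white, dark=dark)
    return cube, refs, Mask(true_mask, threshold=float("nan"), statistic="ground-truth")
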