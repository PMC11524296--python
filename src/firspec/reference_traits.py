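"""Wet-lab ground-truth formulas for needle chlorophyll and water content.

Chlorophyll is extracted in 95% ethanol and quantified from absorbance at
665 and 649 nm with the standard two-wavelength coefficients:

    Ca (mg/L) = 13.95*D665 - 6.88*D649
    Cb (mg/L) = 24.96*D649 - 7.32*D665
    CT = Ca + Cb
    LCC (mg/g) = CT * (VT/1000) * BT / W

VT is the extract volume in mL; dividing by 1000 bridges mg/L x L -> mg so
LCC comes out in mg per g fresh weight (the formula as usually printed leaves
this unit conversion implicit).  Absorbance at 470 nm is read on the plate
alongside but feeds no formula here; it is carried through for QC.

Water content is gravimetric: LWC = (M1 - M2)/M1 with M1 the fresh and M2 the
oven-dry needle weight, returned as a fraction (render as percent at the
formatting boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError


@dataclass(frozen=True)
class AbsorbanceReading:
    d665: float
    d649: float
    d470: float = 0.0       # read but unused by the formulas; kept for QC
    vt_ml: float = 10.0     # extract volume, mL
    bt: float = 1.0         # dilution ratio
    fresh_weight_g: float = 0.3

    def __post_init__(self) -> None:
        vals = (self.d665, self.d649, self.d470, self.vt_ml, self.bt, self.fresh_weight_g)
        if not all(np.isfinite(vals)):
            raise InvalidConfigError("absorbance reading fields must be finite")
        if min(self.d665, self.d649, self.d470) < 0:
            raise InvalidConfigError("absorbances must be >= 0")
        if self.fresh_weight_g <= 0:
            raise InvalidConfigError("fresh weight must be positive")
        if self.bt < 1:
            raise InvalidConfigError("dilution ratio must be >= 1")


@dataclass(frozen=True)
class ChlorophyllResult:
    ca: float       # chlorophyll a, mg/L
    cb: float       # chlorophyll b, mg/L
    ct: float       # total, mg/L (= ca + cb always)
    lcc: float      # mg per g fresh weight
    suspect: bool   # True when a concentration came out negative


@dataclass(frozen=True)
class LeafWeights:
    m1_fresh_g: float
    m2_dry_g: float

    def __post_init__(self) -> None:
        if self.m1_fresh_g <= 0:
            raise InvalidConfigError("fresh weight must be positive")
        if not (0 <= self.m2_dry_g <= self.m1_fresh_g):
            raise InvalidConfigError("dry weight must lie in [0, fresh weight]")


def chlorophyll_content(reading: AbsorbanceReading) -> ChlorophyllResult:
    """Two-wavelength ethanol-extract chlorophyll, flagged (not clamped) if negative."""
    ca = 13.95 * reading.d665 - 6.88 * reading.d649
    cb = 24.96 * reading.d649 - 7.32 * reading.d665
    ct = ca + cb
    lcc = ct * (reading.vt_ml / 1000.0) * reading.bt / reading.fresh_weight_g
    return ChlorophyllResult(ca, cb, ct, lcc, suspect=bool(min(ca, cb, ct) < 0))


def leaf_water_content(weights: LeafWeights) -> float:
    """Gravimetric water fraction (M1 - M2)/M1 in [0, 1]."""
    return (weights.m1_fresh_g - weights.m2_dry_g) / weights.m1_fresh_g


_LAB_COLUMNS = ["sample_id", "d665", "d649", "d470", "vt_ml", "bt",
                "fresh_weight_g", "m1_g", "m2_g"]


def traits_from_lab_sheet(path: str | Path) -> pd.DataFrame:
    """Compute the trait table (sample_id, lcc, lwc, suspect) from a lab-sheet CSV."""
    df = pd.read_csv(path)
    missing = [c for c in _LAB_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidConfigError(f"lab sheet missing columns: {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        chl = chlorophyll_content(
            AbsorbanceReading(rec.d665, rec.d649, rec.d470, rec.vt_ml, rec.bt,
                              rec.fresh_weight_g)
        )
        lwc = leaf_water_content(LeafWeights(rec.m1_g, rec.m2_g))
        rows.append({"sample_id": rec.sample_id, "lcc": chl.lcc, "lwc": lwc,
                     "suspect": chl.suspect})
    return pd.DataFrame(rows)
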