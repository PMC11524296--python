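"""Characteristic wavelengths reported by the Chinese fir seedling study this
package's synthetic generator emulates.

These are inputs, not outputs: the original raw spectra are not public, but
the published characteristic-wavelength lists (SPA and CARS, for LCC and LWC,
on the 512-band 870-1720 nm instrument grid) are, and the band-retention
fractions quoted alongside them can be recomputed by counting these lists
against the grid size.
"""

from __future__ import annotations

INSTRUMENT_N_BANDS = 512

SPA_LCC_WAVELENGTHS_NM = (
    873.5, 1387.6, 1394.2, 1425.7, 1577.4, 1651.4, 1671.1, 1689.2, 1697.4, 1702.3,
)

SPA_LWC_WAVELENGTHS_NM = (
    873.5, 895.3, 917.0, 968.8, 1289.9, 1389.3, 1394.2, 1575.7, 1653.0, 1689.2,
    1695.8, 1700.7, 1702.3,
)

CARS_LCC_WAVELENGTHS_NM = (
    880.2, 881.9, 883.6, 885.3, 890.3, 953.8, 955.5, 957.1, 958.8, 962.2,
    967.2, 1137.2, 1138.8, 1142.2, 1152.2, 1153.8, 1158.8, 1162.1, 1213.6, 1225.3,
    1231.9, 1233.6, 1424.0, 1430.6, 1432.3, 1433.9, 1435.6, 1542.8, 1544.4, 1546.1,
    1547.7, 1549.4, 1552.7, 1557.6, 1559.3, 1560.9, 1565.9, 1567.5, 1574.1, 1580.7,
    1662.9, 1664.6, 1666.2, 1669.5, 1671.1, 1672.8, 1674.4, 1676.1, 1677.7, 1684.3,
    1699.0, 1700.7, 1702.3,
)

CARS_LWC_WAVELENGTHS_NM = (
    881.9, 883.6, 885.3, 958.8, 1213.6, 1231.9, 1233.6, 1427.3, 1433.9, 1435.6,
    1440.5, 1549.4, 1552.7, 1554.3, 1556.0, 1557.6, 1560.9, 1562.6, 1565.9, 1567.5,
    1580.7, 1664.6, 1669.5, 1671.1, 1672.8, 1674.4, 1676.1, 1700.7, 1702.3,
)


def band_retention_percent(wavelengths, n_bands: int = INSTRUMENT_N_BANDS) -> float:
    """Percentage of the instrument grid a selected wavelength list retains."""
    return 100.0 * len(tuple(wavelengths)) / n_bands
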