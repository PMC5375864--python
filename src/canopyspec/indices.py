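"""Vegetation indices keyed to canopy greenness, chlorophyll absorption,
xanthophyll-cycle light use efficiency and red-edge chlorophyll.

All anchor wavelengths resolve to the nearest band on the cube's grid
(tolerance: twice the grid step), so the formulas written for nominal
wavelengths (531, 550, 570, 670, 700, 720, 800 nm) apply unchanged to a
sensor sampling at ~2.8 nm.

Index definitions:

    NDVI        = (R800 - R670) / (R800 + R670)
    TCARI       = 3 [ (R700 - R670) - 0.2 (R700 - R550) (R700 / R670) ]
    PRI         = (R531 - R570) / (R531 + R570)
    CI_red_edge = R800 / R720 - 1
    EVI         = 2.5 (R800 - R670) / (R800 + 6 R670 - 7.5 R470 + 1)

NDVI and PRI are bounded in [-1, 1] for non-negative spectra; CI_red_edge
and NDVI are invariant to uniform amplitude scaling while TCARI scales
linearly with amplitude — which is exactly why TCARI separates sunlit from
shaded pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedValueError
from .spectra import nearest_band
from .types import HyperCube, Spectrum

VI_NAMES = ("NDVI", "TCARI", "PRI", "CI_red_edge", "EVI")


@dataclass
class VIResult:
    name: str
    value: float
    source_bands: dict = field(default_factory=dict)


def _anchors(wavelengths, targets):
    return {t: nearest_band(wavelengths, t) for t in targets}


def _r(spectrum: Spectrum, bands: dict) -> dict:
    return {t: float(spectrum.values[i]) for t, i in bands.items()}


def ndvi(s: Spectrum) -> VIResult:
    """Normalized difference vegetation index."""
    bands = _anchors(s.wavelengths, (800, 670))
    r = _r(s, bands)
    denom = r[800] + r[670]
    if denom == 0:
        raise UndefinedValueError("NDVI undefined: R800 + R670 = 0")
    return VIResult("NDVI", (r[800] - r[670]) / denom, bands)


def tcari(s: Spectrum) -> VIResult:
    """Transformed chlorophyll absorption reflectance index."""
    bands = _anchors(s.wavelengths, (700, 670, 550))
    r = _r(s, bands)
    if r[670] == 0:
        raise UndefinedValueError("TCARI undefined: R670 = 0")
    value = 3.0 * ((r[700] - r[670]) - 0.2 * (r[700] - r[550]) * (r[700] / r[670]))
    return VIResult("TCARI", value, bands)


def pri(s: Spectrum) -> VIResult:
    """Photochemical reflectance index."""
    bands = _anchors(s.wavelengths, (531, 570))
    r = _r(s, bands)
    denom = r[531] + r[570]
    if denom == 0:
        raise UndefinedValueError("PRI undefined: R531 + R570 = 0")
    return VIResult("PRI", (r[531] - r[570]) / denom, bands)


def ci_red_edge(s: Spectrum) -> VIResult:
    """Red edge chlorophyll index."""
    bands = _anchors(s.wavelengths, (800, 720))
    r = _r(s, bands)
    if r[720] == 0:
        raise UndefinedValueError("CI_red_edge undefined: R720 = 0")
    return VIResult("CI_red_edge", r[800] / r[720] - 1.0, bands)


def evi(s: Spectrum) -> VIResult:
    """Enhanced vegetation index (standard coefficients 2.5/6/7.5/1,
    anchors 800/670/470 nm); used for the non-vegetation mask."""
    bands = _anchors(s.wavelengths, (800, 670, 470))
    r = _r(s, bands)
    denom = r[800] + 6.0 * r[670] - 7.5 * r[470] + 1.0
    if denom == 0:
        raise UndefinedValueError("EVI undefined: zero denominator")
    return VIResult("EVI", 2.5 * (r[800] - r[670]) / denom, bands)


_VI_FUNCS = {
    "NDVI": ndvi,
    "TCARI": tcari,
    "PRI": pri,
    "CI_red_edge": ci_red_edge,
    "EVI": evi,
}


def vi_spectrum(s: Spectrum, name: str) -> VIResult:
    """Dispatch a VI by name."""
    return _VI_FUNCS[name.upper() if name.upper() in _VI_FUNCS else name](s)


def vi_image(cube: HyperCube, name: str, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel VI map.  Masked-out or undefined pixels are NaN.

    Vectorized over the anchor-band images; numerically identical to
    calling the single-spectrum function per pixel.
    """
    if name not in _VI_FUNCS:
        raise KeyError(f"unknown VI {name!r}; choose from {VI_NAMES}")
    wl = cube.wavelengths
    data = cube.data.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if name == "NDVI":
            r800 = data[:, :, nearest_band(wl, 800)]
            r670 = data[:, :, nearest_band(wl, 670)]
            out = (r800 - r670) / (r800 + r670)
        elif name == "TCARI":
            r700 = data[:, :, nearest_band(wl, 700)]
            r670 = data[:, :, nearest_band(wl, 670)]
            r550 = data[:, :, nearest_band(wl, 550)]
            out = 3.0 * ((r700 - r670) - 0.2 * (r700 - r550) * (r700 / r670))
        elif name == "PRI":
            r531 = data[:, :, nearest_band(wl, 531)]
            r570 = data[:, :, nearest_band(wl, 570)]
            out = (r531 - r570) / (r531 + r570)
        elif name == "CI_red_edge":
            r800 = data[:, :, nearest_band(wl, 800)]
            r720 = data[:, :, nearest_band(wl, 720)]
            out = r800 / r720 - 1.0
        else:  # EVI
            r800 = data[:, :, nearest_band(wl, 800)]
            r670 = data[:, :, nearest_band(wl, 670)]
            r470 = data[:, :, nearest_band(wl, 470)]
            out = 2.5 * (r800 - r670) / (r800 + 6.0 * r670 - 7.5 * r470 + 1.0)
    out = np.where(np.isfinite(out), out, np.nan)
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return out
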