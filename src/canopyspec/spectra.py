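"""Spectral primitives: band lookup, continuum removal, class means.

Continuum removal divides a spectrum by its upper convex hull over a
wavelength window, isolating the shape of pigment absorption features from
overall amplitude.  Two windows matter for rice canopies: the carotenoid
feature in the blue (400-550 nm) and the chlorophyll feature in the red
(550-750 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BandLookupError, UndefinedValueError, WindowError
from .types import Spectrum, SpectralLibrary


@dataclass(frozen=True)
class ContinuumWindow:
    """A closed wavelength interval [low, high] in nm for continuum removal."""

    low: float
    high: float
    name: str = ""


#: Carotenoid absorption window.
BLUE_WINDOW = ContinuumWindow(400.0, 550.0, "blue")
#: Chlorophyll absorption window.
RED_WINDOW = ContinuumWindow(550.0, 750.0, "red")


def nearest_band(wavelengths, target: float, tol: float = None) -> int:
    """Index of the band closest to ``target`` nm.

    Real grids sample at ~2.8 nm, so index formulas naming exact
    wavelengths (670 nm, 800 nm ...) resolve to the nearest band.  Ties
    break toward the lower wavelength.  ``tol`` defaults to twice the
    median grid step; a miss larger than ``tol`` raises
    :class:`BandLookupError`.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if tol is None:
        tol = 2.0 * float(np.median(np.diff(wl)))
    if tol <= 0:
        raise ValueError("tol must be > 0")
    dist = np.abs(wl - target)
    idx = int(np.argmin(dist))  # argmin takes the first (lower-wavelength) tie
    if dist[idx] > tol:
        raise BandLookupError(
            f"no band within {tol} nm of {target} nm (nearest: {wl[idx]} nm)"
        )
    return idx


def _window_slice(spectrum: Spectrum, window: ContinuumWindow):
    mask = (spectrum.wavelengths >= window.low) & (spectrum.wavelengths <= window.high)
    if mask.sum() < 3:
        raise WindowError(
            f"window [{window.low}, {window.high}] nm covers only "
            f"{int(mask.sum())} bands (need >= 3)"
        )
    return spectrum.wavelengths[mask], spectrum.values[mask]


def _upper_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the upper convex hull vertices of (x, y), x ascending.

    Andrew's monotone chain, upper chain only.  Collinear points are
    dropped, so the hull is the minimal vertex set; the first and last
    points are always vertices.
    """
    hull = []
    for i in range(len(x)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # keep only right turns (convex from above)
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.array(hull)


def continuum_hull(spectrum: Spectrum, window: ContinuumWindow) -> Spectrum:
    """Upper convex hull of the spectrum over ``window``, evaluated at every
    in-window band by linear interpolation between hull vertices."""
    wl, vals = _window_slice(spectrum, window)
    vertices = _upper_hull(wl, vals)
    hull_vals = np.interp(wl, wl[vertices], vals[vertices])
    # hull never dips below the data (guards float fuzz at vertices)
    return Spectrum(wl, np.maximum(hull_vals, vals))


def continuum_remove(spectrum: Spectrum, window: ContinuumWindow) -> Spectrum:
    """Continuum-removed spectrum: values / hull, in (0, 1], exactly 1 at
    hull-touch points including both window endpoints."""
    wl, vals = _window_slice(spectrum, window)
    hull = continuum_hull(spectrum, window).values
    if np.any(hull <= 0):
        raise UndefinedValueError("continuum hull reaches zero; cannot divide")
    return Spectrum(wl, vals / hull)


def band_depth(cr_spectrum: Spectrum) -> float:
    """1 - min of a continuum-removed spectrum; deeper = stronger absorption."""
    return float(1.0 - cr_spectrum.values.min())


def class_mean_spectrum(
    library: SpectralLibrary, class_name: str, stage: str | None = None
) -> Spectrum:
    """Pointwise mean spectrum of one class (optionally one stage)."""
    entries = library.select(class_name, stage)
    stack = np.vstack([s.values for _, _, s in entries])
    return Spectrum(library.wavelengths, stack.mean(axis=0))


def local_minima_count(values) -> int:
    """Number of strict interior local minima (plateaus count once)."""
    v = np.asarray(values, dtype=float)
    count = 0
    i = 1
    n = len(v)
    while i < n - 1:
        # skip over flat runs
        j = i
        while j < n - 1 and v[j + 1] == v[j]:
            j += 1
        if v[i - 1] > v[i] and j < n - 1 and v[j + 1] > v[j]:
            count += 1
        i = j + 1
    return count
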