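"""Radiometric calibration, MNF denoising, band subsetting, vegetation mask.

The preprocessing chain for a raw scene is::

    cube_dn -> calibrate -> mnf_denoise -> subset_bands(400, 900) -> evi_mask

Calibration converts digital numbers to relative reflectance against a
white reference panel:

    Ref_target = (DN_target - DN_noise) / (DN_panel - DN_noise) * Ref_panel

Output reflectance is deliberately not clipped: specular pixels may exceed
the panel and downstream operations tolerate values slightly above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, ConfigurationError, WindowError
from .indices import vi_image
from .types import HyperCube


@dataclass
class CalibrationSet:
    """Dark-current DN, white-panel DN and panel reflectance, per band.

    Scalars broadcast across bands.
    """

    dn_noise: np.ndarray
    dn_panel: np.ndarray
    ref_panel: np.ndarray

    def __post_init__(self):
        self.dn_noise = np.atleast_1d(np.asarray(self.dn_noise, dtype=float))
        self.dn_panel = np.atleast_1d(np.asarray(self.dn_panel, dtype=float))
        self.ref_panel = np.atleast_1d(np.asarray(self.ref_panel, dtype=float))
        if np.any(self.ref_panel <= 0) or np.any(self.ref_panel > 1):
            raise ConfigurationError("ref_panel must be in (0, 1]")


def calibrate(cube: HyperCube, cal: CalibrationSet) -> HyperCube:
    """DN -> relative reflectance against the white reference panel."""
    if cube.units_flag != "dn":
        raise CalibrationError("calibrate expects a DN cube")
    denom = cal.dn_panel - cal.dn_noise
    if np.any(denom <= 0):
        raise CalibrationError("dn_panel must exceed dn_noise at every band")
    refl = (cube.data.astype(float) - cal.dn_noise) / denom * cal.ref_panel
    # dark-noise fluctuation can push DN below the dark reference;
    # reflectance stays >= 0 by construction of the physical quantity
    refl = np.clip(refl, 0.0, None)
    return HyperCube(refl, cube.wavelengths, "reflectance", dict(cube.metadata))


def _shift_difference_noise(flat: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Noise covariance from horizontal first differences / sqrt(2).

    Adjacent pixels along a row share signal, so their difference is
    dominated by noise; /sqrt(2) makes the difference variance match the
    per-pixel noise variance.
    """
    img = flat.reshape(rows, cols, -1)
    diffs = (img[:, 1:, :] - img[:, :-1, :]) / np.sqrt(2.0)
    d = diffs.reshape(-1, flat.shape[1])
    d = d - d.mean(axis=0)
    return d.T @ d / max(d.shape[0] - 1, 1)


def _regularize(cov: np.ndarray) -> np.ndarray:
    eps = 1e-10 * np.trace(cov)
    if eps <= 0:
        eps = 1e-12
    return cov + eps * np.eye(cov.shape[0])


def mnf_denoise(cube: HyperCube, k: int | None = None) -> HyperCube:
    """Minimum-noise-fraction smoothing: forward transform, keep the top
    ``k`` components by signal-to-noise, inverse transform.

    Noise covariance is estimated by along-row shift differences; data are
    whitened by the noise, eigen-decomposed, and reconstructed from the
    ``k`` leading components.  With ``k`` = band count this is the identity
    (up to round-off).  ``k=None`` keeps components whose noise-whitened
    eigenvalue exceeds 1 (i.e., SNR above the noise floor).
    """
    rows, cols, bands = cube.data.shape
    if cols < 2:
        raise ConfigurationError("MNF needs >= 2 columns for noise estimation")
    if k is not None and not (1 <= k <= bands):
        raise ConfigurationError(f"k must be in [1, {bands}]")
    flat = cube.data.reshape(-1, bands).astype(float)
    mu = flat.mean(axis=0)
    centered = flat - mu

    noise_cov = _regularize(_shift_difference_noise(flat, rows, cols))
    # whiten by noise: F = E L^{-1/2} from the noise eigensystem
    nvals, nvecs = np.linalg.eigh(noise_cov)
    nvals = np.clip(nvals, 1e-18 * nvals.max(), None)
    whiten = nvecs / np.sqrt(nvals)
    data_cov = centered.T @ centered / max(centered.shape[0] - 1, 1)
    white_cov = whiten.T @ data_cov @ whiten
    evals, evecs = np.linalg.eigh(white_cov)
    order = np.argsort(evals)[::-1]  # decreasing SNR
    evals, evecs = evals[order], evecs[:, order]

    if k is None:
        k = max(int(np.sum(evals > 1.0)), 1)
    fwd = whiten @ evecs  # bands -> MNF components
    inv = np.linalg.pinv(fwd)  # components -> bands
    scores = centered @ fwd[:, :k]
    recon = scores @ inv[:k, :] + mu
    if cube.units_flag == "reflectance":
        recon = np.clip(recon, 0.0, None)
    return HyperCube(
        recon.reshape(rows, cols, bands),
        cube.wavelengths,
        cube.units_flag,
        dict(cube.metadata),
    )


def subset_bands(cube: HyperCube, low: float = 400.0, high: float = 900.0) -> HyperCube:
    """Keep bands with low <= lambda <= high (default: the 400-900 nm range
    retained after discarding the noisy grid edges)."""
    if low >= high:
        raise ConfigurationError("low must be < high")
    mask = (cube.wavelengths >= low) & (cube.wavelengths <= high)
    if not mask.any():
        raise WindowError(f"no bands inside [{low}, {high}] nm")
    return HyperCube(
        cube.data[:, :, mask],
        cube.wavelengths[mask],
        cube.units_flag,
        dict(cube.metadata),
    )


def evi_mask(cube: HyperCube, threshold: float = 0.45) -> np.ndarray:
    """Boolean vegetation mask: True where EVI > threshold (strict)."""
    if cube.units_flag != "reflectance":
        raise ConfigurationError("EVI mask needs a reflectance cube")
    evi = vi_image(cube, "EVI")
    return np.where(np.isfinite(evi), evi > threshold, False)
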