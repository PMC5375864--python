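"""Synthetic labeled hyperspectral scenes and plot-level agronomic truth.

Stands in for field images of rice canopies.  Each canopy component class
(sunlit leaf SL, shaded leaf SHL, sunlit panicle SP, shaded panicle SHP)
is modeled as a smooth reflectance plateau — a visible baseline rising
through a logistic red-edge ramp to a NIR plateau — multiplied by Gaussian
pigment absorption features:

    R(l) = shade * plateau(l) * prod_i (1 - depth_i * boost * G_i(l)) * noise

Shading has two independent effects, matching the physics of diffuse
irradiance and within-canopy multiple scattering:

* an amplitude factor ``shade_factor`` < 1 (weaker irradiance), and
* an absorption-depth multiplier ``absorption_boost`` > 1 (longer optical
  path deepens apparent pigment absorption).

Leaves carry one blue (chlorophyll + carotenoid) and one red (chlorophyll)
absorption band; panicles are pigment-poor (roughly an order of magnitude
less chlorophyll), brighter in the visible, and carry a pair of narrow
carotenoid bands in the blue that produce their characteristic double-peak
continuum-removed absorption feature.

Pigment-band depths are tied monotonically to leaf chlorophyll content
(LCC), with a saturating curve for sunlit leaves and an LCC-dependent
boost for shaded ones, so that vegetation-index-vs-chlorophyll regressions
are recoverable from generated seasons — and are stronger for shaded
pixels, the pattern the analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .types import (
    CLASS_CODES,
    COMPONENT_CLASSES,
    STAGES,
    HyperCube,
    LabelMap,
    PlotRecord,
    Spectrum,
)

# SPAD -> LCC line used to keep generated truth self-consistent
_SPAD_SLOPE = 1.4498
_SPAD_INTERCEPT = -22.014


@dataclass
class ComponentModel:
    """Parametric reflectance model for one canopy component class."""

    name: str
    nir_plateau: float
    vis_baseline: float
    pigment_bands: list  # [(center nm, width nm, depth 0-1), ...]
    shade_factor: float = 1.0
    absorption_boost: float = 1.0
    pixel_noise_sd: float = 0.02
    amplitude_jitter_sd: float = 0.0
    ramp_center: float = 700.0
    ramp_width: float = 18.0
    #: relative slope of the visible baseline per nm; > 0 for the
    #: yellowish panicle tissue whose reflectance rises toward the red
    vis_slope: float = 0.0
    #: sd of the per-pixel random NIR tilt (leaf angle / structure
    #: variability reshapes the plateau without touching the visible)
    nir_tilt_sd: float = 0.0

    def __post_init__(self):
        if not (0 < self.shade_factor <= 1):
            raise ConfigurationError("shade_factor must be in (0, 1]")
        if self.name in ("SL", "SP") and self.shade_factor != 1.0:
            raise ConfigurationError("sunlit classes must have shade_factor = 1")
        if self.absorption_boost < 1:
            raise ConfigurationError("absorption_boost must be >= 1")
        if not (0 < self.vis_baseline < self.nir_plateau < 1):
            raise ConfigurationError("need 0 < vis_baseline < nir_plateau < 1")
        for c, w, d in self.pigment_bands:
            if not (0 <= d < 1) or d * self.absorption_boost >= 1:
                raise ConfigurationError(
                    f"band at {c} nm: depth*boost must stay in [0, 1)"
                )
            if w <= 0:
                raise ConfigurationError("band width must be > 0")


@dataclass
class SceneConfig:
    """Size, stage, class mixture, wavelength grid and seed of one scene."""

    rows: int
    cols: int
    stage: str | None = None
    class_fractions: dict | None = None
    wl_start: float = 400.0
    wl_stop: float = 900.0
    wl_step: float = 2.8
    seed: int = 0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("scene must be at least 1x1")
        if self.stage is not None and self.stage not in STAGES:
            raise ConfigurationError(f"unknown stage {self.stage!r}")
        if not (self.wl_start <= 400 and self.wl_stop >= 900):
            raise ConfigurationError("wavelength span must cover [400, 900] nm")
        if self.class_fractions is not None:
            fr = self.class_fractions
            if any(v < 0 for v in fr.values()):
                raise ConfigurationError("class fractions must be nonnegative")
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ConfigurationError("class fractions must sum to 1")

    def grid(self) -> np.ndarray:
        return np.arange(self.wl_start, self.wl_stop + 1e-9, self.wl_step)


@dataclass
class Scene:
    """One generated image with its ground truth."""

    plot_id: str
    stage: str
    cube: HyperCube
    labels: LabelMap
    record: PlotRecord | None = None


def plateau_profile(grid: np.ndarray, model: ComponentModel) -> np.ndarray:
    """Smooth baseline: visible floor rising through the red edge to the
    NIR plateau (logistic ramp centered near 700 nm)."""
    ramp = 1.0 / (1.0 + np.exp(-(grid - model.ramp_center) / model.ramp_width))
    vis = model.vis_baseline * (1.0 + model.vis_slope * (grid - 400.0))
    return vis + (model.nir_plateau - vis) * ramp


def _absorption(grid: np.ndarray, model: ComponentModel) -> np.ndarray:
    factor = np.ones_like(grid)
    for center, width, depth in model.pigment_bands:
        g = np.exp(-((grid - center) ** 2) / (2.0 * width**2))
        factor *= 1.0 - depth * model.absorption_boost * g
    return factor


def component_batch(
    model: ComponentModel, grid: np.ndarray, rng: np.random.Generator, n: int
) -> np.ndarray:
    """``n`` noisy spectra of one component as an (n, bands) array."""
    clean = model.shade_factor * plateau_profile(grid, model) * _absorption(grid, model)
    if clean.max() >= 1.0 or clean.min() <= 0.0:
        raise ConfigurationError("model parameters drive reflectance outside (0, 1)")
    out = np.tile(clean, (n, 1))
    if model.amplitude_jitter_sd > 0:
        out *= np.exp(rng.normal(0.0, model.amplitude_jitter_sd, size=(n, 1)))
    if model.nir_tilt_sd > 0:
        # pixel-specific linear reshaping of the NIR plateau only
        ramp = 1.0 / (1.0 + np.exp(-(grid - model.ramp_center) / model.ramp_width))
        tilt = rng.normal(0.0, model.nir_tilt_sd, size=(n, 1))
        out *= 1.0 + tilt * ramp * (grid - 800.0) / 100.0
    if model.pixel_noise_sd > 0:
        out *= np.exp(rng.normal(0.0, model.pixel_noise_sd, size=out.shape))
    return np.clip(out, 1e-6, 0.999999)


def component_spectrum(
    model: ComponentModel, grid, rng: np.random.Generator | None = None
) -> Spectrum:
    """One spectrum of a component (noise-free if all noise params are 0)."""
    grid = np.asarray(grid, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    return Spectrum(grid, component_batch(model, grid, rng, 1)[0])


# ---------------------------------------------------------------------------
# stage-dependent default models

#: Leaf NIR plateau rises to heading (HD) then falls; panicle NIR is
#: approximately stage-constant.
_LEAF_NIR = {"ET": 0.46, "FT": 0.48, "JT": 0.50, "BT": 0.52, "HD": 0.54, "FL": 0.49}
_PANICLE_NIR = 0.42

#: Stage-typical leaf chlorophyll content (ug/cm^2) used when a caller
#: does not supply plot-level truth: rise-fall with peak at HD and a
#: local minimum at jointing (JT).
STAGE_LCC = {"ET": 36.0, "FT": 40.0, "JT": 38.0, "BT": 44.0, "HD": 46.0, "FL": 39.0}

#: Stage-typical leaf area index (m^2/m^2); peaks at booting so that
#: canopy chlorophyll (LCC x LAI) peaks at BT while LCC peaks at HD.
STAGE_LAI = {"ET": 0.7, "FT": 1.7, "JT": 2.7, "BT": 4.2, "HD": 3.7, "FL": 2.7}

_SHADE_FACTOR = 0.5


def _leaf_depths(lcc: float):
    """Saturating depth-vs-chlorophyll curves for sunlit leaves: absorption
    is already near-saturated at field LCC, which is what makes sunlit
    TCARI a weak chlorophyll proxy."""
    d_blue = 0.78 * (1.0 - np.exp(-lcc / 10.0))
    d_red = 0.72 * (1.0 - np.exp(-lcc / 6.0))
    return float(d_blue), float(d_red)


def _shade_boost(lcc: float, shade_coupling: float) -> float:
    """Absorption boost for shaded classes; its LCC dependence is the knob
    that couples shading with a stronger VI-chlorophyll linkage."""
    return 1.0 + 0.10 + shade_coupling * (lcc - 30.0)


def default_component_models(
    stage: str, lcc: float | None = None, shade_coupling: float = 0.008
) -> dict:
    """The four component models at one growth stage.

    Encodes the qualitative contrasts of real canopies: sunlit amplitude
    above shaded at every band, panicles brighter than leaves in the
    visible, shaded absorption deeper than sunlit, leaf NIR rising to HD
    then falling, panicle NIR stage-constant, and panicle pigment depths
    far below leaf depths.
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    if lcc is None:
        lcc = STAGE_LCC[stage]
    d_blue, d_red = _leaf_depths(lcc)
    boost = _shade_boost(lcc, shade_coupling)
    leaf_bands = [(445.0, 30.0, d_blue), (668.0, 50.0, d_red)]
    # panicles: ~12x less pigment, but Beer-law saturation means the red
    # absorption depth falls far less than 12x; the carotenoid pair in the
    # blue produces the double-peak CR feature
    pan_red = 0.84 * (1.0 - np.exp(-lcc / 55.0))
    pan_bands = [
        (450.0, 14.0, 0.30),
        (488.0, 14.0, 0.33),
        (660.0, 45.0, float(pan_red)),
    ]
    leaf_nir = _LEAF_NIR[stage]
    common = dict(pixel_noise_sd=0.02, amplitude_jitter_sd=0.06, nir_tilt_sd=0.10)
    return {
        "SL": ComponentModel(
            "SL", leaf_nir, 0.13, leaf_bands, 1.0, 1.0, ramp_center=710.0, **common
        ),
        "SHL": ComponentModel(
            "SHL", leaf_nir, 0.13, leaf_bands, _SHADE_FACTOR, boost,
            ramp_center=710.0, **common
        ),
        "SP": ComponentModel(
            "SP", _PANICLE_NIR, 0.22, pan_bands, 1.0, 1.0, vis_slope=3.0e-3, **common
        ),
        "SHP": ComponentModel(
            "SHP", _PANICLE_NIR, 0.22, pan_bands, _SHADE_FACTOR, boost,
            vis_slope=3.0e-3, **common
        ),
    }


def default_class_fractions(stage: str) -> dict:
    """Areal class fractions.  Early tillering canopies are open (more
    sunlit than shaded foliage); closed canopies after tillering carry
    far more shaded than sunlit leaf area."""
    if stage == "ET":
        return {"SL": 0.36, "SHL": 0.22, "SP": 0.05, "SHP": 0.07, "NONVEG": 0.30}
    return {"SL": 0.14, "SHL": 0.34, "SP": 0.10, "SHP": 0.12, "NONVEG": 0.30}


def soil_spectrum_batch(grid: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    """Flat, slightly red-sloped soil/water background; EVI well below the
    0.45 vegetation threshold."""
    base = 0.05 + 8e-5 * (grid - 400.0)
    out = np.tile(base, (n, 1))
    out *= np.exp(rng.normal(0.0, 0.03, size=out.shape))
    return np.clip(out, 1e-6, 0.999999)


def generate_scene(config: SceneConfig, models: dict | None = None):
    """Generate one labeled scene: a reflectance cube plus truth labels.

    Pixels are assigned classes by sampling ``class_fractions``; each
    vegetation pixel draws a spectrum from its class model and NONVEG
    pixels get the soil background.  Deterministic for a fixed seed.
    """
    stage = config.stage or "HD"
    if models is None:
        models = default_component_models(stage)
    fractions = config.class_fractions or default_class_fractions(stage)
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    names = list(fractions)
    probs = np.array([fractions[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    draw = rng.choice(len(names), size=(config.rows, config.cols), p=probs)
    labels = np.zeros((config.rows, config.cols), dtype=np.int32)
    data = np.zeros((config.rows, config.cols, grid.size))
    for i, name in enumerate(names):
        pix = np.nonzero(draw == i)
        npix = len(pix[0])
        labels[pix] = CLASS_CODES[name]
        if npix == 0:
            continue
        if name == "NONVEG":
            data[pix] = soil_spectrum_batch(grid, rng, npix)
        else:
            data[pix] = component_batch(models[name], grid, rng, npix)
    cube = HyperCube(data, grid, "reflectance", {"stage": stage})
    return cube, LabelMap(labels, dict((v, k) for k, v in CLASS_CODES.items()))


_N_RATES = ("N0", "N1", "N2", "N3")
_N_LCC_OFFSET = {"N0": -5.0, "N1": -2.0, "N2": 1.0, "N3": 3.5}
_N_LAI_FACTOR = {"N0": 0.6, "N1": 0.85, "N2": 1.05, "N3": 1.25}


def generate_season(
    base_config: SceneConfig, n_plots: int = 1, shade_coupling: float = 0.008
):
    """A full growing season: one scene + one PlotRecord per plot per stage.

    Plot-level LCC follows the rise-fall seasonal curve (peak at heading,
    local minimum at jointing) shifted by nitrogen rate; LAI peaks at
    booting so canopy chlorophyll content peaks there.  SPAD readings are
    drawn around the target and LCC/CCC recomputed from them, keeping the
    SPAD -> LCC -> CCC chain exactly self-consistent.
    """
    if n_plots < 1:
        raise ConfigurationError("n_plots must be >= 1")
    rng = np.random.default_rng(base_config.seed)
    scenes, records = [], []
    for p in range(n_plots):
        n_rate = _N_RATES[p % len(_N_RATES)]
        for stage in STAGES:
            lcc_target = (
                STAGE_LCC[stage] + _N_LCC_OFFSET[n_rate] + rng.normal(0.0, 0.4)
            )
            spad_target = (lcc_target - _SPAD_INTERCEPT) / _SPAD_SLOPE
            readings = spad_target + rng.normal(0.0, 0.8, size=(3, 3))
            spad_mean = float(np.mean(readings.mean(axis=1)))
            lcc = _SPAD_SLOPE * spad_mean + _SPAD_INTERCEPT
            lai = STAGE_LAI[stage] * _N_LAI_FACTOR[n_rate] * float(
                np.exp(rng.normal(0.0, 0.05))
            )
            ccc = lcc * lai * 0.01
            record = PlotRecord(
                plot_id=f"P{p + 1:02d}",
                stage=stage,
                n_rate=n_rate,
                spad_readings=readings,
                lcc=lcc,
                lai=lai,
                ccc=ccc,
            )
            models = default_component_models(stage, lcc=lcc, shade_coupling=shade_coupling)
            cfg = SceneConfig(
                rows=base_config.rows,
                cols=base_config.cols,
                stage=stage,
                class_fractions=base_config.class_fractions,
                wl_start=base_config.wl_start,
                wl_stop=base_config.wl_stop,
                wl_step=base_config.wl_step,
                seed=int(rng.integers(2**31)),
            )
            cube, labels = generate_scene(cfg, models)
            scenes.append(Scene(record.plot_id, stage, cube, labels, record))
            records.append(record)
    return scenes, records


def records_to_frame(records) -> "object":
    """PlotRecords as a tidy pandas DataFrame (plots.csv layout)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in records],
            "stage": [r.stage for r in records],
            "n_rate": [r.n_rate for r in records],
            "spad_mean": [float(np.mean(r.spad_readings)) for r in records],
            "lcc": [r.lcc for r in records],
            "lai": [r.lai for r in records],
            "ccc": [r.ccc for r in records],
        }
    )
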