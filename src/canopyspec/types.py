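"""Core data containers shared by every pipeline stage.

All spectral data live on a wavelength grid in nanometres, strictly
increasing.  Reflectance is relative (unitless, nominally 0-1 but not
clipped above 1: specular pixels may exceed the white-panel reference).
Raw sensor output is kept as digital numbers (DN, counts) until
radiometric calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SelectionError

#: The four canopy component classes: sunlit leaf, shaded leaf,
#: sunlit panicle, shaded panicle.  Fixed order — ties in classification
#: are broken toward the earlier class.
COMPONENT_CLASSES = ("SL", "SHL", "SP", "SHP")

#: Integer codes used in classification rasters.
CLASS_CODES = {"UNLABELED": 0, "SL": 1, "SHL": 2, "SP": 3, "SHP": 4, "NONVEG": 5}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}

#: The six phenological stages: early tillering, fully tillering,
#: jointing, booting, heading, filling.
STAGES = ("ET", "FT", "JT", "BT", "HD", "FL")


def _as_wavelengths(wavelengths) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ConfigurationError("wavelength grid must be 1-D with >= 2 points")
    if not np.all(np.diff(wl) > 0):
        raise ConfigurationError("wavelengths must be strictly increasing")
    return wl


@dataclass
class Spectrum:
    """A single reflectance spectrum: wavelengths (nm) and values.

    The atomic unit of all spectral math.  Values must be finite and
    non-negative; the grid strictly increasing.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.wavelengths = _as_wavelengths(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ConfigurationError(
                f"values shape {self.values.shape} != wavelengths "
                f"shape {self.wavelengths.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("spectrum values must be finite")
        if np.any(self.values < 0):
            raise ConfigurationError("spectrum values must be >= 0")

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Spectrum)
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class HyperCube:
    """A hyperspectral image: rows x cols x bands array plus wavelength grid.

    ``units_flag`` is ``"dn"`` for raw counts or ``"reflectance"`` after
    calibration.  ``metadata`` is a free-form string map (acquisition date,
    stage label, exposure ...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    units_flag: str = "dn"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = _as_wavelengths(self.wavelengths)
        if self.data.ndim != 3:
            raise ConfigurationError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavelengths.size:
            raise ConfigurationError(
                f"cube has {self.data.shape[2]} bands but "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.units_flag not in ("dn", "reflectance"):
            raise ConfigurationError(f"unknown units_flag {self.units_flag!r}")
        if self.units_flag == "reflectance":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and finite.min() < 0:
                raise ConfigurationError("reflectance cube has negative values")

    @property
    def shape(self):
        return self.data.shape

    def pixel(self, row: int, col: int) -> Spectrum:
        """Spectrum of one pixel (0-based row/col, row 0 at top)."""
        return Spectrum(self.wavelengths, np.clip(self.data[row, col], 0, None))


@dataclass
class LabelMap:
    """Per-pixel class codes plus the code -> class-name table."""

    labels: np.ndarray
    code_table: dict

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ConfigurationError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.code_table)
        if missing:
            raise ConfigurationError(f"codes {sorted(missing)} missing from code_table")

    def count(self, class_name: str) -> int:
        codes = [c for c, n in self.code_table.items() if n == class_name]
        if not codes:
            return 0
        return int(np.isin(self.labels, codes).sum())


@dataclass
class SpectralLibrary:
    """Labeled ROI spectra: (class name, stage label, Spectrum) entries.

    All member spectra share one wavelength grid.
    """

    entries: list  # list[(class_name, stage, Spectrum)]
    classes: tuple = COMPONENT_CLASSES

    def __post_init__(self):
        if not self.entries:
            raise ConfigurationError("spectral library must have >= 1 entry")
        grid = self.entries[0][2].wavelengths
        for cls, stage, spec in self.entries:
            if cls not in self.classes:
                raise ConfigurationError(f"class {cls!r} not in {self.classes}")
            if not np.array_equal(spec.wavelengths, grid):
                raise ConfigurationError("library spectra on differing grids")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.entries[0][2].wavelengths

    def select(self, class_name: str | None = None, stage: str | None = None):
        """Entries matching the class and/or stage filters."""
        out = [
            e
            for e in self.entries
            if (class_name is None or e[0] == class_name)
            and (stage is None or e[1] == stage)
        ]
        if not out:
            raise SelectionError(
                f"no library entries for class={class_name!r} stage={stage!r}"
            )
        return out

    def stages(self) -> list:
        seen = []
        for _, stage, _ in self.entries:
            if stage not in seen:
                seen.append(stage)
        return seen


@dataclass
class Thresholds:
    """Decision-tree split values: the PRI leaf/panicle split and the two
    TCARI sunlit/shaded splits (one within leaves, one within panicles)."""

    pri_split: float
    tcari_leaf_split: float
    tcari_panicle_split: float

    def __post_init__(self):
        for name in ("pri_split", "tcari_leaf_split", "tcari_panicle_split"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


@dataclass
class PlotRecord:
    """Per-plot agronomic truth for one stage.

    ``spad_readings`` is the 3 leaves x 3 readings protocol; ``lcc`` is leaf
    chlorophyll content (ug/cm^2) derived from the mean SPAD, ``lai`` leaf
    area index (m^2/m^2) and ``ccc`` canopy chlorophyll content (g/m^2)
    = LCC x LAI x 0.01.
    """

    plot_id: str
    stage: str
    n_rate: str
    spad_readings: np.ndarray  # shape (3, 3)
    lcc: float
    lai: float
    ccc: float

    def __post_init__(self):
        self.spad_readings = np.asarray(self.spad_readings, dtype=float)
        if self.spad_readings.shape != (3, 3):
            raise ConfigurationError("spad_readings must be 3 leaves x 3 readings")
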