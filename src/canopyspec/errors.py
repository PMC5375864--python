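"""Exception hierarchy shared across the pipeline."""


class CanopySpecError(Exception):
    """Base class for all package errors."""


class FormatError(CanopySpecError):
    """A file does not conform to the expected on-disk format."""


class CorruptionError(FormatError):
    """Declared dimensions disagree with the payload actually on disk."""


class BandLookupError(CanopySpecError, KeyError):
    """No band close enough to a requested wavelength."""


class WindowError(CanopySpecError):
    """A spectral window contains too few bands for the operation."""


class CalibrationError(CanopySpecError):
    """Radiometric calibration inputs are inconsistent (panel <= dark)."""


class UndefinedValueError(CanopySpecError, ArithmeticError):
    """A spectral index is undefined for this input (zero denominator)."""


class SelectionError(CanopySpecError, LookupError):
    """A class/stage selection matched no library entries."""


class ConfigurationError(CanopySpecError, ValueError):
    """Generator or pipeline parameters are out of their legal range."""


class DerivationError(CanopySpecError):
    """Threshold derivation is impossible (a class or stage is missing)."""


class StratificationError(CanopySpecError):
    """A class has fewer samples than cross-validation folds."""


class FitError(CanopySpecError):
    """A regression could not be fitted (degenerate input or no convergence)."""
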