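"""Exception hierarchy shared by all pipeline stages."""


class NirscalError(Exception):
    """Base class for all package errors."""


class ParseError(NirscalError):
    """Malformed input file (ragged row, non-numeric cell, duplicate id)."""


class GridError(NirscalError):
    """Wavelength grid is non-monotone, non-uniform, or mismatched."""


class RangeError(NirscalError):
    """Reference value outside the admissible [0, 100] %DM range."""


class ProfileError(NirscalError):
    """Infeasible simulation profile (bounds, SDs, band placement)."""


class IdentifiabilityError(ProfileError):
    """Two constituents were given (near-)proportional absorptivity curves."""


class DegenerateSpectrumError(NirscalError):
    """A spectrum with no variance where variance is required (SNV, MSC)."""


class WindowError(NirscalError):
    """Spectrum shorter than the combined smoothing/derivative window."""


class ModelError(NirscalError):
    """Regression cannot proceed (zero-variance target, grid mismatch...)."""


class ScreeningError(NirscalError):
    """Outlier screening failed (too few samples, everything flagged)."""


class SplitError(NirscalError):
    """Calibration/validation split cannot be formed."""
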