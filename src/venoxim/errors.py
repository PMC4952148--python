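"""Exception hierarchy shared across the package."""


class VenoximError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VenoximError, ValueError):
    """An argument violates a precondition (negative path, non-positive intensity...)."""


class DegenerateSignalError(VenoximError):
    """The signal carries no usable modulation (e.g. zero infrared change)."""


class NonInvertibleError(VenoximError):
    """The saturation inversion has a vanishing denominator at this ratio."""


class ConfigError(VenoximError, ValueError):
    """A configuration object violates its invariants."""


class ResampleRequiredError(VenoximError):
    """The time base is not uniform; resample before spectral analysis."""


class SeparationInfeasibleError(VenoximError):
    """Pulse and stimulation bands overlap; the stimulation frequency must move."""


class InsufficientDataError(VenoximError):
    """Too few cycles (or none) to form an estimate."""


class ConstantSeriesError(VenoximError):
    """Correlation is undefined for a constant series."""


class AlignmentError(VenoximError):
    """Paired inputs have mismatched lengths or windows."""
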