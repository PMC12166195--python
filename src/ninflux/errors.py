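"""Exception hierarchy.

Every error raised by this package derives from :class:`NinfluxError`, so
callers can catch the package's failures with a single except clause while
still distinguishing configuration mistakes from data problems and fit
failures.
"""


class NinfluxError(Exception):
    """Base class for all ninflux errors."""


class DomainError(NinfluxError, ValueError):
    """An argument is outside its mathematical domain (e.g. negative S)."""


class ConfigurationError(NinfluxError, ValueError):
    """An option, design or grid is invalid or incomplete."""


class SchemaError(ConfigurationError):
    """A tabular input does not match the declared column schema."""


class ParseError(ConfigurationError):
    """A cell in a tabular input could not be parsed; message carries line numbers."""


class InsufficientDataError(NinfluxError, ValueError):
    """Not enough distinct design points to identify the requested model."""


class DegenerateDataError(NinfluxError, ValueError):
    """Data carry no usable signal (e.g. all observed rates are zero)."""


class FitFailureError(NinfluxError, RuntimeError):
    """The optimizer failed to converge at every threshold candidate."""


class ComparisonError(NinfluxError, ValueError):
    """Model comparison requested between fits of different datasets."""


class MeasurementError(NinfluxError, ValueError):
    """Physically inconsistent measurement (e.g. sample enrichment above source)."""


class PhaseOrderWarning(UserWarning):
    """Phase parameters were given with Km1 > Km2 and have been swapped."""
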