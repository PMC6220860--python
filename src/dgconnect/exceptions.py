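"""Exception hierarchy.

Everything raised on bad user input or degenerate data derives from
:class:`DGConnectError`, so callers can catch one type at the CLI boundary.
"""


class DGConnectError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DGConnectError):
    """Invalid configuration: bad shapes, unknown region names, out-of-range parameters."""


class TableFormatError(DGConnectError):
    """A tabular input file violates the expected layout (named row/column context included)."""


class MissingDataError(DGConnectError):
    """A required (animal, region) measurement is absent."""


class DegenerateDataError(DGConnectError):
    """Data admit no meaningful estimate (zero variance, response orthogonal to predictors, ...)."""


class CalibrationError(DGConnectError):
    """Standards cannot support a monotone optical-density -> activity mapping."""


class CalibrationRangeError(CalibrationError):
    """Query outside the calibrated optical-density range with extrapolation disabled."""


class QuantificationError(DGConnectError):
    """Uptake-ratio computation impossible (e.g. zero whole-brain denominator)."""
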