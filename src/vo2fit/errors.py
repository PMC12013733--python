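"""Exception hierarchy.

Distinct classes so the CLI can map configuration, data, and numerical
failures to distinct exit codes.
"""


class Vo2FitError(Exception):
    """Base class for all package errors."""


class ConfigError(Vo2FitError):
    """Invalid configuration: missing columns, bad bounds, bad flags."""


class FormatError(Vo2FitError):
    """Unparseable input content (e.g. a time token), with row context."""


class InsufficientDataError(Vo2FitError):
    """Too few valid samples to proceed."""


class UnitError(Vo2FitError):
    """Unit-mode violation, e.g. relative series without body mass."""


class DegenerateSeriesError(Vo2FitError):
    """Series carries no usable kinetic signal (constant, or peak <= baseline)."""


class UndefinedStatisticError(Vo2FitError):
    """A statistic's preconditions are violated (zero variance, n <= k+1, ...)."""
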