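"""Exception hierarchy shared across the package."""


class TiterflowError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TiterflowError, ValueError):
    """An argument is outside its documented domain."""


class MissingChannelError(TiterflowError, KeyError):
    """A channel name referenced by a ChannelMap is absent from the table."""

    def __init__(self, channel: str, available=()):
        self.channel = channel
        self.available = tuple(available)
        msg = f"channel {channel!r} not found"
        if available:
            msg += f" (available: {', '.join(self.available)})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class InsufficientDataError(TiterflowError, ValueError):
    """Too few events or data points for the requested operation."""


class DegenerateDataError(TiterflowError, ValueError):
    """Input is constant or otherwise degenerate for the requested fit."""


class UndefinedRatioError(TiterflowError, ZeroDivisionError):
    """A fold/percent metric is undefined because its denominator is <= 0."""


class FcsFormatError(TiterflowError, ValueError):
    """The FCS file is malformed or uses an unsupported feature."""


class NonConvergenceError(TiterflowError, RuntimeError):
    """Iterative fit failed to converge; carries the best partial fit."""

    def __init__(self, message: str, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class ConfigError(TiterflowError, ValueError):
    """Pipeline configuration failed validation; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field {field!r}: {message}")
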