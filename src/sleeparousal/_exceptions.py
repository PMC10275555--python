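"""Exception hierarchy shared across the package."""


class SleepArousalError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SleepArousalError, ValueError):
    """An input violates a documented precondition or invariant."""


class PlacementError(SleepArousalError):
    """Requested arousal events cannot be placed without overlap."""


class FormatError(SleepArousalError):
    """A file is not in a recognised container format."""


class ChannelNotFoundError(SleepArousalError, LookupError):
    """The requested channel is absent from the recording."""


class ConfigurationError(SleepArousalError):
    """A configuration is internally inconsistent (e.g. input too small
    for the backbone's reduction chain)."""


class UndefinedMetricError(SleepArousalError, ZeroDivisionError):
    """A ratio metric has a zero denominator (e.g. specificity with no
    negative samples); raised instead of silently returning zero."""
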