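"""Exception hierarchy shared across the package."""


class QuadgaitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(QuadgaitError):
    """An input table is missing required columns or has an unusable layout."""


class EventValidationError(QuadgaitError):
    """Footfall events violate ordering or contact/lift interleaving."""


class MissingDataError(QuadgaitError):
    """A marker track does not cover the requested time interval."""


class InsufficientDataError(QuadgaitError):
    """Too few samples to compute the requested statistic."""


class UndefinedStatisticError(QuadgaitError):
    """The statistic is undefined for the given input (e.g. zero standard error)."""


class ConfigError(QuadgaitError):
    """Invalid configuration or scenario parameters."""
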