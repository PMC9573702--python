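"""Exception hierarchy shared across the package."""


class GelquantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GelquantError, ValueError):
    """An object violates one of its structural invariants."""


class FormatError(ValidationError):
    """An input file is structurally malformed (duplicate ids, bad header)."""


class NormalizationError(GelquantError, ValueError):
    """Total-density normalization cannot be carried out (e.g. zero gel total)."""


class ConsistencyError(GelquantError, ValueError):
    """Outputs from different pipeline stages do not refer to the same data."""


class UndefinedEffectError(GelquantError, ValueError):
    """An effect statistic is undefined for the given group means."""


class ConfigError(GelquantError, ValueError):
    """A settings object carries an invalid combination of values."""
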