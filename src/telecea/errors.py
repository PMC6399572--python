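"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, SchemaError -> 3,
numerical failures (ParameterError, UndefinedMeanError) -> 4.
"""


class TeleceaError(Exception):
    """Base class for all package errors."""


class ParameterError(TeleceaError, ValueError):
    """Invalid numeric parameter (negative rate, zero lifetime, bad probability)."""


class ConfigError(TeleceaError):
    """Malformed or inconsistent configuration file."""


class SchemaError(TeleceaError):
    """Tabular input violating the documented schema; message carries the line number."""


class MissingMainModeError(TeleceaError):
    """Consultation record without a main transport mode; cost must be imputed."""


class UndefinedMeanError(TeleceaError):
    """A mean was requested over zero complete observations."""
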