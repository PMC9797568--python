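"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError /
FormatError -> 3, any other StressweaveError -> 4.
"""


class StressweaveError(Exception):
    """Base class for all package errors."""


class ParameterError(StressweaveError, ValueError):
    """An argument is outside its documented domain."""


class ConfigError(StressweaveError):
    """Pipeline configuration is invalid (unknown keys, bad thresholds)."""


class FormatError(StressweaveError):
    """An input file does not parse under its declared dialect."""


class DataError(StressweaveError):
    """A file parses but its contents violate a data contract."""


class NormalizationError(StressweaveError):
    """A normalizing constant is zero while values still differ."""
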