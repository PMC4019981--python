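"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3, StageError -> 4.
"""


class ApmsError(Exception):
    """Base class for all package errors."""


class ConfigError(ApmsError):
    """Invalid configuration value or unknown configuration key."""


class DataError(ApmsError):
    """Invalid input data."""


class SchemaError(DataError):
    """A required column or field is missing from an input table."""


class ValidationError(DataError):
    """A row or record violates a data-model invariant."""


class StageError(ApmsError):
    """A pipeline stage failed; the message names the stage."""
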