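"""Exception hierarchy used across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError
(and subclasses) -> 3.
"""


class ErpDecodeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ErpDecodeError):
    """Invalid configuration value or combination (windows, rates, keys)."""


class DataError(ErpDecodeError):
    """Input data violate a precondition (shape, labels, emptiness)."""


class ChannelError(DataError):
    """A required channel label is missing."""


class FilterError(DataError):
    """Signal too short (or otherwise unsuitable) for the requested filter."""
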