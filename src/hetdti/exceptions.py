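"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigurationError -> 2,
DataValidationError -> 3, NumericalError -> 4.
"""


class HetdtiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HetdtiError):
    """Invalid or inconsistent configuration (unknown keys, missing networks, bad modes)."""


class DataValidationError(HetdtiError):
    """Input data violates a structural contract (shape, range, symmetry, unknown ids)."""


class ParseError(DataValidationError):
    """A file could not be parsed; the message names the offending line."""


class NumericalError(HetdtiError):
    """A numerical routine failed (singular system, diverging loss)."""
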