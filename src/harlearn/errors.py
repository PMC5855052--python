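"""Exception hierarchy used across the toolkit."""


class HarlearnError(Exception):
    """Base class for all toolkit errors."""


class ParseError(HarlearnError):
    """A delimited-text file could not be parsed (message carries the line)."""


class SchemaError(HarlearnError):
    """A file was parsed but does not match the declared column schema."""


class SpecError(HarlearnError, ValueError):
    """Invalid parameter combination (window sizes, architecture dims, ...)."""


class DataError(HarlearnError):
    """Data content makes an operation impossible (e.g. an all-missing channel)."""


class InputError(HarlearnError, ValueError):
    """An array argument violates an operation's preconditions."""


class IntegrityError(HarlearnError):
    """Features and labels (or similar paired structures) are inconsistent."""


class TrainingError(HarlearnError):
    """A model cannot be trained on the given data (e.g. a single class)."""
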