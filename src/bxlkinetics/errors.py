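"""Exception hierarchy and warning categories."""


class BxlKineticsError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(BxlKineticsError, ValueError):
    """An argument violates a documented precondition (non-positive
    concentration, zero reaction time, ...)."""


class InsufficientDataError(BxlKineticsError):
    """Too few distinct observations to identify the model parameters."""


class MissingDataError(BxlKineticsError):
    """A required record (e.g. a substrate DP) is absent from a series."""


class ParseError(BxlKineticsError):
    """A file row could not be interpreted; the message names the row."""


class SchemaError(ParseError):
    """A file header does not match the expected column schema."""


class ConfigurationError(BxlKineticsError):
    """A pipeline configuration is incomplete or contains unknown keys."""


class SubstrateDepletionWarning(UserWarning):
    """The linear endpoint estimate predicts >10% substrate consumption,
    so the measured rate may underestimate the true initial rate."""
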