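"""Exception types shared across the package."""


class ScreenweightError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ScreenweightError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(ScreenweightError):
    """Too few observations for the requested model."""


class SchemaError(ScreenweightError):
    """An input table does not match its documented column contract."""


class ConvergenceError(ScreenweightError):
    """An iterative fit failed in a way that cannot be reported as a result."""
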