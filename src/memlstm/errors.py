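"""Exception types shared across the package."""


class MemLSTMError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MemLSTMError, ValueError):
    """A value passed to an operation is non-finite, empty or out of domain."""


class ConfigError(MemLSTMError, ValueError):
    """A configuration value violates its contract (e.g. dt <= 0)."""


class ShapeError(MemLSTMError, ValueError):
    """Array dimensions do not chain consistently."""


class RangeError(MemLSTMError, ValueError):
    """A weight exceeds the representable conductance range."""


class InsufficientDataError(MemLSTMError, ValueError):
    """A recording is too short for the requested operation."""


class DegenerateInputError(MemLSTMError, ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


class DivergenceError(MemLSTMError, RuntimeError):
    """Training produced a non-finite loss."""
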