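"""Exception hierarchy shared across the package."""


class NriqaError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NriqaError, ValueError):
    """A function argument violates its contract."""


class InvalidInputError(NriqaError, ValueError):
    """Input data (image, matrix, vector) violates a precondition."""


class ConfigurationError(NriqaError, ValueError):
    """A configuration value or key is unknown or inconsistent."""


class ConstraintViolationError(NriqaError):
    """A resource budget (FLOPs, memory) would be exceeded."""


class OptimizationError(NriqaError):
    """The optimizer encountered a non-finite fitness value."""


class BackendError(NriqaError):
    """A deep-feature backend failed during a forward pass."""


class StateError(NriqaError):
    """An operation was called on an object in the wrong state."""


class UndefinedStatisticError(NriqaError, ValueError):
    """A statistic is undefined for the given input (e.g. constant vector)."""


class IOFormatError(NriqaError, IOError):
    """An image or table file could not be read or written."""
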