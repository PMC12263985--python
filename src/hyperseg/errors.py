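"""Exception hierarchy shared across the package."""


class HypersegError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HypersegError, ValueError):
    """A parameter value is outside its admissible set (non-finite, zero normal, ...)."""


class DomainError(HypersegError, ValueError):
    """A point lies outside the mathematical domain of an operation (e.g. off the ball)."""


class DegenerateInputError(HypersegError, ValueError):
    """Inputs make the operation numerically degenerate (vanishing denominator)."""


class ConfigurationError(HypersegError, ValueError):
    """Inconsistent model / training / patch configuration."""


class InputError(HypersegError, ValueError):
    """Malformed user-supplied data (shape or spacing mismatch, missing file)."""


class UndefinedMetricError(HypersegError, ValueError):
    """The requested metric is undefined for these inputs (e.g. empty surface)."""
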