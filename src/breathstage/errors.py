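"""Exception hierarchy shared across the pipeline stages."""


class BreathstageError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(BreathstageError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(BreathstageError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class StateError(BreathstageError, RuntimeError):
    """An operation was invoked on an object in the wrong state."""


class DegenerateInputError(BreathstageError, ValueError):
    """Input is structurally valid but too degenerate to process."""


class NumericError(BreathstageError, ArithmeticError):
    """A computation produced a non-finite value."""


class InternalError(BreathstageError, RuntimeError):
    """An invariant the pipeline guarantees internally was violated."""
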