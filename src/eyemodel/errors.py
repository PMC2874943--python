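"""Exception hierarchy for the eye-model pipeline."""


class EyeModelError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EyeModelError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(EyeModelError, ValueError):
    """Input geometry is degenerate (e.g. near-isotropic point set)."""


class OutOfRangeError(EyeModelError, ValueError):
    """Evaluation requested outside the supported domain."""


class InvalidStateError(EyeModelError, RuntimeError):
    """Operation not valid for the object's current state (e.g. units)."""


class NumericFailureError(EyeModelError, ArithmeticError):
    """A numeric computation produced NaN/Inf or lost meaning."""


class DivergenceError(NumericFailureError):
    """A time integration diverged; carries the offending step index."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
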