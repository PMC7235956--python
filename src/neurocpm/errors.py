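"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when data handed to an operation violates its preconditions."""


class InvalidSpecError(ValueError):
    """Raised when a generator or run specification is internally inconsistent."""


class NumericalError(ArithmeticError):
    """Raised when a numerical step (e.g. precision-matrix inversion) fails."""
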