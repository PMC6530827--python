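"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when user-supplied parameters violate their contracts."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative estimator fails to converge.

    Carries the last relative change so the caller can judge how far
    the solver was from the tolerance.
    """

    def __init__(self, message: str, last_change: float | None = None):
        super().__init__(message)
        self.last_change = last_change


class ParseError(ValueError):
    """Raised on malformed input files; message carries the offending location."""
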