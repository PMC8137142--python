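"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class SizingError(ValueError):
    """Raised when requested geometry cannot fit the available field of view."""


class ConsistencyError(RuntimeError):
    """Raised when internal bookkeeping disagrees with itself."""
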