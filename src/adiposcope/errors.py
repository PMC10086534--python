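"""Exception hierarchy shared across the package."""


class AdiposcopeError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(AdiposcopeError):
    """Raised when image/mask/plane shapes are inconsistent."""


class ValidationError(AdiposcopeError):
    """Raised when a parameter or spec violates its invariants."""


class ConvergenceError(AdiposcopeError):
    """Raised when an iterative algorithm fails to converge."""


class UndefinedFieldError(AdiposcopeError):
    """Raised when a per-field quantity is undefined (e.g. zero denominator)."""


class FitError(AdiposcopeError):
    """Raised when a nonlinear fit fails or the data are degenerate."""
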