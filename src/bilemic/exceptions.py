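"""Exception hierarchy.

``ValidationError`` marks bad inputs (CLI exit code 2), ``FitError`` and its
subclasses mark analyses that could not be completed (CLI exit code 3).
"""


class BilemicError(Exception):
    """Base class for all package errors."""


class ValidationError(BilemicError, ValueError):
    """Invalid input data or parameters."""


class FitError(BilemicError, RuntimeError):
    """An analysis stage failed to produce a result."""


class ConvergenceError(FitError):
    """A numerical solver failed to converge (pathological parameters)."""


class NoTransitionError(FitError):
    """No demicellization transition detected in the scanned concentration range."""


class NoBreakpointError(FitError):
    """A surface-tension curve is statistically consistent with a single line."""


class InsufficientDataError(FitError):
    """Too few usable points remain for a fit."""
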