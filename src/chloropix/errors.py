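"""Exception hierarchy.

Validation problems (bad annotations, wrong pixel counts, malformed inputs)
derive from :class:`ValidationError`; failures of the numerics themselves
(singular fits, non-convergent solves) derive from :class:`NumericalError`.
The command-line layer maps the former to exit code 2 and the latter to 3.
"""


class ChloropixError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChloropixError, ValueError):
    """Input violates a documented contract."""


class InvalidPixelError(ValidationError):
    """A pixel cannot be used for green-pixel-intensity computation."""


class AnnotationError(ValidationError):
    """A photograph annotation is malformed (empty/overlapping regions ...)."""


class GeometryError(AnnotationError):
    """An annotated region extends outside the image."""


class NumericalError(ChloropixError, ArithmeticError):
    """A numerical procedure failed (singular fit, non-convergence)."""


class SingularFitError(NumericalError):
    """Regression design is degenerate (e.g. all x identical)."""


class InvalidCurveError(NumericalError):
    """A calibration curve cannot be inverted (slope <= 0)."""
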