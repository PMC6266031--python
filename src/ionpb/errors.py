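"""Exception hierarchy shared across the package."""


class IonpbError(Exception):
    """Base class for all package errors."""


class ValidationError(IonpbError):
    """Invalid input data, file content, or configuration."""


class DatabaseError(ValidationError):
    """Beam-database content violates its invariants."""


class GeometryError(IonpbError):
    """Degenerate geometry (zero direction, empty ROI, point off grid...)."""


class FitError(IonpbError):
    """Non-convergent parameter fit; carries the best residual achieved."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class ConvergenceError(IonpbError):
    """Iterative optimisation failed to meet its stopping rule.

    Carries the convergence trace so the caller can inspect progress.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
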