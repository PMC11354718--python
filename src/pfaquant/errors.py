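"""Exception hierarchy for pfaquant."""


class PfaQuantError(Exception):
    """Base class for all package errors."""


class SceneValidationError(PfaQuantError):
    """A scene/config field violates a physical or schema invariant."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ResolutionError(PfaQuantError):
    """Grid too coarse to resolve a geometric feature."""


class ConfigurationError(PfaQuantError):
    """Solver setup invalid (e.g. missing ground electrode)."""


class ConvergenceError(PfaQuantError):
    """Iterative solve did not reach tolerance; carries residual history."""

    def __init__(self, message: str, residual_history=None):
        self.residual_history = list(residual_history or [])
        super().__init__(message)


class PlaneRangeError(PfaQuantError):
    """Requested plane or point lies outside the solved domain."""


class MetricError(PfaQuantError):
    """A lesion metric is undefined for the given input (e.g. empty mask)."""


class GeometryError(PfaQuantError):
    """Polygon/contour geometry invalid (self-intersection, zero-length line)."""
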