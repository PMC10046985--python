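"""Exception hierarchy used across the package."""


class VesselTortError(Exception):
    """Base class for all package errors."""


class ParameterError(VesselTortError, ValueError):
    """An argument violates a stated precondition (bad window, offsets, ...)."""


class CurveLengthError(VesselTortError, ValueError):
    """Curve too short for the derivative-estimation stencil."""


class DomainError(VesselTortError, ValueError):
    """Geometric parameters outside the domain of the index formulas."""


class DegenerateCurveError(VesselTortError, ValueError):
    """Curve violates regularity: the estimated speed drops to (numerical) zero."""


class DegenerateInputError(VesselTortError, ValueError):
    """Degenerate geometry, e.g. a closed curve with zero chord."""


class SegmentationError(VesselTortError, RuntimeError):
    """Binarization failed to produce a vessel component joining the endpoints."""


class TopologyError(VesselTortError, RuntimeError):
    """Skeleton topology is unusable (disconnected principals, no path)."""


class AmbiguousEndpointError(VesselTortError, RuntimeError):
    """Both tentative endpoints map to the same skeleton candidate."""


class DegenerateTestError(VesselTortError, ValueError):
    """A statistical test is undefined (zero variance)."""


class UndefinedCorrelationError(VesselTortError, ValueError):
    """Correlation requested on a constant column."""


class ConfigError(VesselTortError, ValueError):
    """Invalid or incomplete study configuration."""
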