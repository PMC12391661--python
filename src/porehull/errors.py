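"""Exception hierarchy shared across the package."""


class PorehullError(Exception):
    """Base class for all errors raised by porehull."""


class TrackFormatError(PorehullError, ValueError):
    """A trajectory table is malformed (e.g. a required column is missing)."""


class TrackValidationError(PorehullError, ValueError):
    """A track or track set violates an invariant (monotonic time, unique ids, ...)."""


class DomainError(PorehullError, ValueError):
    """A physical or geometric parameter is outside its valid domain."""


class InfeasibleGeometryError(DomainError):
    """The tracer bead does not fit inside the confinement geometry."""


class DegenerateGeometryError(PorehullError, ValueError):
    """A point cloud is affinely degenerate (collinear in 2D, coplanar in 3D)."""


class FitError(PorehullError, ValueError):
    """A model fit failed (too few points, negative plateau intercept, ...)."""


class NonConfinedError(FitError):
    """No MSD plateau detected: the curve does not look confined."""


class SwellingInfeasibleError(DomainError):
    """Swelling masses are inconsistent with the polymer-network model."""
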