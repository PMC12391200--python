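"""Exception hierarchy shared across the package."""


class DiscBiphasicError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DiscBiphasicError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SeriesConvergenceError(DiscBiphasicError, RuntimeError):
    """A truncated series failed to reach the requested tolerance."""


class SolverError(DiscBiphasicError, RuntimeError):
    """A numerical solver produced a non-finite or diverging solution."""


class DataQualityError(DiscBiphasicError, ValueError):
    """An experimental trace violates basic plausibility checks."""


class ImplausibleWeightsError(DiscBiphasicError, ValueError):
    """Buoyancy weights yield a porosity outside the physical range."""


class MeshError(DiscBiphasicError, ValueError):
    """Mesh generation produced degenerate (non-positive Jacobian) elements."""
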