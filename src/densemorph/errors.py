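"""Exception hierarchy shared across the package."""


class DenseMorphError(Exception):
    """Base class for all densemorph errors."""


class InvalidMeshError(DenseMorphError, ValueError):
    """A mesh violates a structural invariant (index range, degenerate face, ...)."""


class MeshFormatError(DenseMorphError, ValueError):
    """A mesh file is unreadable or malformed."""


class DegenerateGeometryError(DenseMorphError, ValueError):
    """Geometry too degenerate for the requested operation (collinear landmarks, ...)."""


class TopologyMismatchError(DenseMorphError, ValueError):
    """Meshes or correspondence maps do not share the required topology."""


class RegistrationDivergenceError(DenseMorphError, RuntimeError):
    """A registration objective worsened persistently; carries the objective trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class UnbalancedDesignError(DenseMorphError, ValueError):
    """A repeated-measures layout is incomplete or unbalanced."""


class MissingLandmarkError(DenseMorphError, ValueError):
    """A required landmark name is absent from a configuration."""
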