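"""Exception hierarchy shared across the ribalign modules."""


class RibalignError(Exception):
    """Base class for all ribalign-specific errors."""


class GeometryError(RibalignError):
    """Spacing/origin/shape disagreement between volumes or masks."""


class DegenerateInputError(RibalignError):
    """Input carries no usable signal (constant volume, empty mask, rank-deficient landmarks)."""


class SizingError(RibalignError):
    """A requested grid cannot contain the requested geometry."""


class UnknownLandmarkError(RibalignError):
    """A landmark name is not in the candidate list."""


class CapacityError(RibalignError):
    """More fracture sites requested than the rib geometry can host."""


class PairingError(RibalignError):
    """Model and patient landmark sets cannot be put in correspondence."""


class ParameterError(RibalignError):
    """A numeric parameter is outside its documented domain."""


class OffSurfaceError(RibalignError):
    """A point lies farther from the surface than the projection tolerance."""


class ConnectivityError(RibalignError):
    """Two points fall on disconnected components of a surface."""


class EmptySceneError(RibalignError):
    """No above-air structure found in a volume."""
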