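"""Exception hierarchy shared across the package."""


class CrownPhenoError(Exception):
    """Base class for all package errors."""


class MeshFormatError(CrownPhenoError):
    """A mesh file could not be parsed; message names the offending line."""


class EmptyMeshError(CrownPhenoError):
    """An operation received a mesh with no faces."""


class NotWatertightError(CrownPhenoError):
    """A closed surface was required; caller should repair with close_holes."""


class CalibrationError(CrownPhenoError):
    """Reference-object scale calibration failed."""


class OrientationError(CrownPhenoError):
    """Stem axis could not be identified; supply the axis manually."""


class DissectionError(CrownPhenoError):
    """Root segmentation or centerline measurement failed."""


class DesignError(CrownPhenoError):
    """An augmented-RCBD design invariant is violated."""


class DomainError(CrownPhenoError):
    """Numeric input outside the valid domain of a trait formula."""
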