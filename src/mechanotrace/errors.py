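"""Exception hierarchy shared across the package."""


class MechanotraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MechanotraceError, ValueError):
    """A parameter is outside its documented range."""


class SingularGeometryError(MechanotraceError):
    """A geometric construction is degenerate (zero separation, collinear angle...)."""


class MinimumImageError(MechanotraceError):
    """A separation exceeds half the smallest box length, so the minimum image is ambiguous."""


class MissingVelocitiesError(MechanotraceError):
    """The kinetic stress term was requested but the trajectory carries no velocities."""


class OutOfDomainError(MechanotraceError):
    """A query point lies outside the grid domain."""


class EmptySurfaceError(MechanotraceError):
    """An isosurface extraction or export found no geometry."""


class StructureParseError(MechanotraceError):
    """A structure file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UnitMismatchError(MechanotraceError):
    """A file declares units other than the package's internal unit system."""


class PipelineDependencyError(MechanotraceError):
    """A pipeline stage was requested before the artifact it depends on exists."""
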