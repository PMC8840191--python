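"""Exception hierarchy shared across the package."""


class VoxelHullError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(VoxelHullError, ValueError):
    """Raised when a geometric solve has no unique solution (e.g. parallel rays)."""


class InputMismatchError(VoxelHullError, ValueError):
    """Raised when paired inputs (cameras/silhouettes/masks) disagree in count or size."""


class EmptyReconstructionError(VoxelHullError, RuntimeError):
    """Raised when a carving stage produces no occupied voxels where some are required."""


class IncompleteSkeletonError(VoxelHullError, ValueError):
    """Raised when a bone endpoint could not be triangulated.

    Attributes
    ----------
    missing : list of str
        Joint names that were required by the bone list but absent.
    """

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"bone endpoints could not be triangulated: {self.missing}")


class EmptyProjectionError(VoxelHullError, ValueError):
    """Raised when a segment projects onto zero pixels in a view (N = 0)."""


class AlignmentError(VoxelHullError, ValueError):
    """Raised when voxel grids to be merged do not share a common lattice."""


class InvalidReferenceError(VoxelHullError, ValueError):
    """Raised when a reference surface is unusable (e.g. missing normals)."""


class CalibrationError(VoxelHullError, ValueError):
    """Raised when a calibration file violates the schema or camera invariants."""
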