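"""Diagnostic exception types raised across the package."""


class StereoCTError(Exception):
    """Base class for all package-specific errors."""


class VolumeError(StereoCTError):
    """Invalid volume geometry or voxel data."""


class DicomReadError(StereoCTError):
    """A DICOM series could not be interpreted as a single uniform CT stack."""


class MixedSeriesError(DicomReadError):
    """Directory contains slices from more than one series."""


class MissingRescaleError(DicomReadError):
    """CT slices lack rescale slope/intercept, HU cannot be recovered."""


class NonUniformSliceStepError(DicomReadError):
    """Slice positions are not evenly spaced along the couch axis."""


class DicomWriteError(StereoCTError):
    """Volume cannot be encoded losslessly into integer DICOM storage."""


class TransformError(StereoCTError):
    """Invalid affine-factor request or transform parameters."""


class MetalNotFoundError(StereoCTError):
    """No voxel above the metal threshold anywhere in the volume."""


class GridMismatchError(StereoCTError):
    """Two volumes that must share a grid do not."""


class ReferenceMismatchError(StereoCTError):
    """Reference slices of the two untilted scans differ beyond tolerance."""

    def __init__(self, ref_superior: int, ref_inferior: int, tolerance: int):
        self.ref_superior = ref_superior
        self.ref_inferior = ref_inferior
        self.tolerance = tolerance
        super().__init__(
            f"reference slice mismatch: superior scan gives {ref_superior}, "
            f"inferior scan gives {ref_inferior}, tolerance {tolerance} slices"
        )


class PhantomError(StereoCTError):
    """Invalid phantom specification (e.g. overlapping structures)."""


class EvaluationError(StereoCTError):
    """Profile/ROI measurement could not be performed."""
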