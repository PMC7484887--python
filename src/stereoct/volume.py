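"""In-memory CT volume container shared by every module.

Axis convention (fixed package-wide):

* ``x`` — left–right (LR), last array axis;
* ``y`` — anterior–posterior (AP), increasing **posteriorly**, middle axis;
* ``z`` — superior–inferior (SI), first array axis, slice index 0 is the
  superior-most slice and the world ``z`` coordinate grows inferiorly.

Voxels hold Hounsfield units, clamped to the 12-bit scanner range
[-1024, 4095]; coordinates are voxel-centre based, world units are mm,
indices are 0-based.  ``tilt_angle_deg`` is the signed gantry tilt the stack
was acquired at (0 for a true axial stack); a tilted stack is stored as an
ordinary array whose slice step is the couch-axis increment, with the angle
kept as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import VolumeError

HU_MIN = -1024.0
HU_MAX = 4095.0
HU_AIR = -1000.0


@dataclass
class Volume:
    """A 3D grid of HU values with physical geometry and tilt metadata.

    Parameters
    ----------
    voxels:
        ``(nz, ny, nx)`` array of Hounsfield units.
    spacing:
        ``(dx, dy, dz)`` voxel spacing in mm (``dz`` is the couch-axis step
        for tilted stacks).
    origin:
        World coordinates ``(x0, y0, z0)`` in mm of the centre of voxel
        ``(z=0, y=0, x=0)``.
    tilt_angle_deg:
        Signed gantry tilt in degrees; positive denotes the "superior" tilt
        direction (the scan whose superior half survives the merge), 0 means
        axial.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tilt_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeError(f"voxels must be 3D (nz, ny, nx), got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise VolumeError("spacing and origin must each have three components")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing components must be strictly positive, got {self.spacing}")
        self.tilt_angle_deg = float(self.tilt_angle_deg)

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape ``(nz, ny, nx)``."""
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge-to-edge size ``(x, y, z)`` of the grid in mm."""
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        return (nx * dx, ny * dy, nz * dz)

    @property
    def center_mm(self) -> tuple[float, float, float]:
        """World coordinates of the grid centre (x, y, z)."""
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        return (
            x0 + (nx - 1) / 2 * dx,
            y0 + (ny - 1) / 2 * dy,
            z0 + (nz - 1) / 2 * dz,
        )

    def index_to_world(self, zyx_index) -> tuple[float, float, float]:
        """Map a (possibly fractional) ``(z, y, x)`` index to world (x, y, z) mm."""
        k, j, i = (float(v) for v in zyx_index)
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        return (x0 + i * dx, y0 + j * dy, z0 + k * dz)

    def world_to_index(self, xyz_mm) -> tuple[float, float, float]:
        """Map world (x, y, z) mm to a fractional ``(z, y, x)`` index."""
        x, y, z = (float(v) for v in xyz_mm)
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        return ((z - z0) / dz, (y - y0) / dy, (x - x0) / dx)

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        """True when shape, spacing and origin match within ``tol`` mm."""
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    # -- value helpers ----------------------------------------------------

    def clamp_hu(self) -> "Volume":
        """Return a copy with voxel values clipped to the storage HU range."""
        return replace(self, voxels=np.clip(self.voxels, HU_MIN, HU_MAX))

    def copy(self) -> "Volume":
        return replace(self, voxels=self.voxels.copy())

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        return replace(self, voxels=voxels)

    def with_tilt(self, tilt_angle_deg: float) -> "Volume":
        return replace(self, voxels=self.voxels, tilt_angle_deg=float(tilt_angle_deg))

    def validate(self) -> None:
        """Raise :class:`VolumeError` if any container invariant is violated."""
        if not np.all(np.isfinite(self.voxels)):
            raise VolumeError("voxels contain non-finite values")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN - 1e-6 or hi > HU_MAX + 1e-6:
            raise VolumeError(f"HU values [{lo}, {hi}] outside storage range [{HU_MIN}, {HU_MAX}]")


@dataclass
class ScanMetadata:
    """Informational acquisition parameters carried alongside a volume.

    Mirrors the protocol entries of a clinical head-and-neck CT acquisition
    (tube voltage, exposure, slice thickness, kernel, rotation time) plus the
    raw tilt tag value as stored in the source file.
    """

    kvp: float | None = None
    mas: float | None = None
    slice_thickness_mm: float | None = None
    recon_kernel: str | None = None
    tube_rotation_s: float | None = None
    tilt_tag_value: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slice_thickness_mm is not None and self.slice_thickness_mm <= 0:
            raise VolumeError("slice_thickness_mm must be > 0")
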