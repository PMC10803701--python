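"""Voxelized 3D scalar lattices with physical spacing and origin.

The array axis order is ``(z, y, x)``; the world coordinate of the center of
voxel ``(0, 0, 0)`` is ``origin_mm`` and all lengths are millimetres.  The
``value_kind`` tag documents what the scalar field means:

========== =================================
activity   MBq/mL
attenuation 1/cm
counts     detected or reconstructed counts
label      integer compartment identifiers
hu         Hounsfield-like CT values
========== =================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .errors import InvalidParameterError

VALUE_KINDS = ("activity", "attenuation", "counts", "label", "hu")


def _as_triplet(v) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(v, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class VoxelVolume:
    """A 3D scalar lattice with voxel spacing and origin.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
    voxel_size_mm : float or 3-tuple (dz, dy, dx), strictly positive
    origin_mm : world position (z, y, x) of the center of voxel (0, 0, 0)
    value_kind : one of :data:`VALUE_KINDS`
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    value_kind: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise InvalidParameterError("values must be a 3D array")
        self.voxel_size_mm = _as_triplet(self.voxel_size_mm)
        if any(s <= 0 for s in self.voxel_size_mm):
            raise InvalidParameterError("voxel sizes must be strictly positive")
        self.origin_mm = _as_triplet(self.origin_mm)
        if self.value_kind not in VALUE_KINDS:
            raise InvalidParameterError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.values.dtype.kind == "f" and not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("voxel values must be finite")

    # -- derived quantities -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in millilitres (mm^3 / 1000)."""
        dz, dy, dx = self.voxel_size_mm
        return dz * dy * dx / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm[axis] * np.arange(n)

    def coordinate_grids(self):
        """Dense (z, y, x) world-coordinate arrays of every voxel center."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def points_xyz(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array of (x, y, z) world coords."""
        zz, yy, xx = self.coordinate_grids()
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def copy(self, **changes) -> "VoxelVolume":
        out = replace(self, **({"values": self.values.copy()} | changes))
        return out

    # -- I/O ----------------------------------------------------------------

    def save(self, path: str) -> None:
        """Write as NIfTI-1, preserving spacing and origin in the affine."""
        dz, dy, dx = self.voxel_size_mm
        affine = np.diag([dx, dy, dz, 1.0]).astype(float)
        # nibabel stores data in (x, y, z) order
        oz, oy, ox = self.origin_mm
        affine[:3, 3] = [ox, oy, oz]
        data = np.ascontiguousarray(np.transpose(self.values, (2, 1, 0)))
        nib.save(nib.Nifti1Image(data, affine), path)

    @classmethod
    def load(cls, path: str, value_kind: str = "counts") -> "VoxelVolume":
        img = nib.load(path)
        data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
        aff = img.affine
        voxel = (abs(aff[2, 2]), abs(aff[1, 1]), abs(aff[0, 0]))
        origin = (aff[2, 3], aff[1, 3], aff[0, 3])
        return cls(np.asarray(data), voxel, origin, value_kind)


def centered_grid(shape, voxel_size_mm, value_kind="counts", dtype=float) -> VoxelVolume:
    """An all-zero volume whose world origin is at the lattice center."""
    shape = tuple(int(s) for s in shape)
    voxel = _as_triplet(voxel_size_mm)
    origin = tuple(-(n - 1) / 2.0 * d for n, d in zip(shape, voxel))
    return VoxelVolume(np.zeros(shape, dtype=dtype), voxel, origin, value_kind)
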