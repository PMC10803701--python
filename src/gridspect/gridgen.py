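"""Parametric grid structures and fillable-volume-fraction accounting.

A *grid* is a periodic arrangement of solid walls inside a fillable
container.  Walls repeat along one to three orthogonal axes with period
``p = t + g`` (wall thickness ``t`` plus gap ``g``).  A point is fillable iff
it falls in the gap for *every* wall axis, so the fillable-volume fraction is
``(g / p) ** k`` for ``k`` wall families.

Three independent routes to the fillable-volume fraction (FVF) are provided:

* :func:`analytic_fvf` — closed form from the design parameters,
* :func:`fvf_from_labels` — voxel counting on a rasterized grid,
* :func:`fvf_from_mass` — mass/density route emulating weighing a print.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    EmptyGeometryError,
    InvalidParameterError,
    SamplingError,
)
from .volume import VoxelVolume

# Label codes used by rasterized grids.
OUTSIDE, FILLABLE, SOLID = 0, 1, 2

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class GridSpec:
    """Design parameters of a periodic wall grid.

    ``wall_axes`` names the axes along which the wall pattern repeats; each
    axis contributes one family of parallel solid walls (walls normal to that
    axis).  ``phase_mm`` offsets the pattern per axis (x, y, z).
    """

    wall_thickness_mm: float
    gap_mm: float
    wall_axes: tuple[str, ...] = ("x", "y")
    phase_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.wall_thickness_mm <= 0 or self.gap_mm <= 0:
            raise InvalidParameterError(
                "wall thickness and gap must both be strictly positive"
            )
        axes = tuple(self.wall_axes)
        if not axes or not set(axes) <= set("xyz") or len(set(axes)) != len(axes):
            raise InvalidParameterError(
                "wall_axes must be a non-empty subset of {'x','y','z'}"
            )
        object.__setattr__(self, "wall_axes", axes)
        object.__setattr__(self, "phase_mm", tuple(float(v) for v in self.phase_mm))

    @property
    def period_mm(self) -> float:
        return self.wall_thickness_mm + self.gap_mm

    def fillable_points(self, points_xyz: np.ndarray) -> np.ndarray:
        """Boolean fillable-mask for an (N, 3) array of (x, y, z) mm points."""
        pts = np.asarray(points_xyz, dtype=float)
        p = self.period_mm
        fillable = np.ones(pts.shape[0], dtype=bool)
        for ax in self.wall_axes:
            i = _AXIS_INDEX[ax]
            u = np.mod(pts[:, i] - self.phase_mm[i], p)
            fillable &= u >= self.wall_thickness_mm
        return fillable


def analytic_fvf(spec: GridSpec | None) -> float:
    """Design fillable-volume fraction ``(g/p)**k``; ``None`` means no grid."""
    if spec is None:
        return 1.0
    frac = spec.gap_mm / spec.period_mm
    return float(frac ** len(spec.wall_axes))


def solve_gap_for_fvf(
    target_fvf: float,
    wall_thickness_mm: float = 2.0,
    wall_axes: Sequence[str] = ("x", "y"),
    phase_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> GridSpec:
    """Invert :func:`analytic_fvf` for the gap at fixed wall thickness.

    Uniform scaling of (t, g) leaves the FVF unchanged, so FVF targeting is
    done by holding ``t`` and solving ``g = t * f / (1 - f)`` with
    ``f = target_fvf ** (1/k)``.
    """
    if not 0.0 < target_fvf < 1.0:
        raise InvalidParameterError("target FVF must lie strictly in (0, 1)")
    if wall_thickness_mm <= 0:
        raise InvalidParameterError("wall thickness must be positive")
    k = len(tuple(wall_axes))
    f = target_fvf ** (1.0 / k)
    gap = wall_thickness_mm * f / (1.0 - f)
    return GridSpec(wall_thickness_mm, gap, tuple(wall_axes), phase_mm)


def solve_wall_for_fvf(
    target_fvf: float,
    period_mm: float = 4.0,
    wall_axes: Sequence[str] = ("x", "y"),
    phase_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> GridSpec:
    """Invert :func:`analytic_fvf` for the wall thickness at fixed period.

    Holding the period fixed keeps the grid spacing well below both the
    imaging resolution and the container size for *any* FVF, whereas holding
    the wall thickness makes high-FVF gaps grow without bound.  Phantom
    builders use this policy.
    """
    if not 0.0 < target_fvf < 1.0:
        raise InvalidParameterError("target FVF must lie strictly in (0, 1)")
    if period_mm <= 0:
        raise InvalidParameterError("period must be positive")
    k = len(tuple(wall_axes))
    f = target_fvf ** (1.0 / k)
    return GridSpec(period_mm * (1.0 - f), period_mm * f, tuple(wall_axes), phase_mm)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ContainerShape:
    """A fillable container defined by a point-membership predicate.

    ``contains`` maps an (N, 3) array of (x, y, z) mm points to booleans.
    ``nominal_volume_ml`` is the design volume of the container without any
    grid (the FVF denominator).
    """

    kind: str
    contains: Callable[[np.ndarray], np.ndarray]
    nominal_volume_ml: float
    bbox_mm: tuple[np.ndarray, np.ndarray]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    params: dict = field(default_factory=dict)

    @staticmethod
    def sphere(diameter_mm: float, center=(0.0, 0.0, 0.0)) -> "ContainerShape":
        if diameter_mm <= 0:
            raise InvalidParameterError("sphere diameter must be positive")
        r = diameter_mm / 2.0
        c = np.asarray(center, dtype=float)

        def contains(pts):
            return np.sum((np.asarray(pts) - c) ** 2, axis=1) <= r * r

        vol = 4.0 / 3.0 * np.pi * r**3 / 1000.0
        return ContainerShape(
            "sphere",
            contains,
            vol,
            (c - r, c + r),
            tuple(c),
            {"diameter_mm": diameter_mm},
        )

    @staticmethod
    def cylinder(
        diameter_mm: float, height_mm: float, center=(0.0, 0.0, 0.0), axis: str = "z"
    ) -> "ContainerShape":
        if diameter_mm <= 0 or height_mm <= 0:
            raise InvalidParameterError("cylinder dimensions must be positive")
        r = diameter_mm / 2.0
        h2 = height_mm / 2.0
        c = np.asarray(center, dtype=float)
        ia = _AXIS_INDEX[axis]
        radial = [i for i in range(3) if i != ia]

        def contains(pts):
            pts = np.asarray(pts) - c
            rad = pts[:, radial[0]] ** 2 + pts[:, radial[1]] ** 2
            return (rad <= r * r) & (np.abs(pts[:, ia]) <= h2)

        lo, hi = c.copy(), c.copy()
        for i in radial:
            lo[i] -= r
            hi[i] += r
        lo[ia] -= h2
        hi[ia] += h2
        vol = np.pi * r**2 * height_mm / 1000.0
        return ContainerShape(
            "cylinder",
            contains,
            vol,
            (lo, hi),
            tuple(c),
            {"diameter_mm": diameter_mm, "height_mm": height_mm, "axis": axis},
        )

    @staticmethod
    def box(size_mm, center=(0.0, 0.0, 0.0)) -> "ContainerShape":
        size = np.broadcast_to(np.asarray(size_mm, dtype=float), (3,)).copy()
        if np.any(size <= 0):
            raise InvalidParameterError("box dimensions must be positive")
        c = np.asarray(center, dtype=float)

        def contains(pts):
            return np.all(np.abs(np.asarray(pts) - c) <= size / 2.0, axis=1)

        vol = float(np.prod(size)) / 1000.0
        return ContainerShape(
            "box", contains, vol, (c - size / 2, c + size / 2), tuple(c), {"size_mm": size}
        )


# ---------------------------------------------------------------------------
# Rasterization and FVF measurement
# ---------------------------------------------------------------------------


def rasterize_grid(
    spec: GridSpec | None,
    container: ContainerShape,
    voxel_size_mm: float,
    pad_voxels: int = 1,
) -> VoxelVolume:
    """Label voxels of the container bounding box as outside/fillable/solid.

    The voxel size must satisfy ``voxel <= min(t, g) / 2`` so both walls and
    gaps are resolved by at least two samples.
    """
    if voxel_size_mm <= 0:
        raise InvalidParameterError("voxel size must be positive")
    if spec is not None:
        limit = min(spec.wall_thickness_mm, spec.gap_mm) / 2.0
        if voxel_size_mm > limit + 1e-12:
            raise SamplingError(
                f"voxel size {voxel_size_mm} mm too coarse: must be <= "
                f"min(t, g)/2 = {limit} mm for min(t, g) = {2 * limit} mm"
            )
    lo, hi = container.bbox_mm
    lo = np.asarray(lo, dtype=float) - pad_voxels * voxel_size_mm
    hi = np.asarray(hi, dtype=float) + pad_voxels * voxel_size_mm
    shape = np.maximum(np.ceil((hi - lo) / voxel_size_mm).astype(int), 1)
    # origin: center of voxel (0,0,0) in (z, y, x) world order
    origin = (lo[2] + voxel_size_mm / 2, lo[1] + voxel_size_mm / 2, lo[0] + voxel_size_mm / 2)
    vol = VoxelVolume(
        np.zeros((shape[2], shape[1], shape[0]), dtype=np.uint8),
        voxel_size_mm,
        origin,
        "label",
    )
    labels = vol.values
    nz = labels.shape[0]
    # process slab-by-slab to bound memory
    for iz in range(nz):
        z = vol.origin_mm[0] + iz * voxel_size_mm
        yy, xx = np.meshgrid(vol.axis_coords(1), vol.axis_coords(2), indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])
        inside = container.contains(pts)
        lab = np.zeros(pts.shape[0], dtype=np.uint8)
        if spec is None:
            lab[inside] = FILLABLE
        else:
            fillable = spec.fillable_points(pts)
            lab[inside & fillable] = FILLABLE
            lab[inside & ~fillable] = SOLID
        labels[iz] = lab.reshape(labels.shape[1:])
    return vol


def fvf_from_labels(labels: VoxelVolume) -> float:
    """FVF = 1 - V_grid / V_container from voxel counts of a label volume."""
    vals = labels.values
    n_fill = int(np.count_nonzero(vals == FILLABLE))
    n_solid = int(np.count_nonzero(vals == SOLID))
    n_container = n_fill + n_solid
    if n_container == 0:
        raise EmptyGeometryError("label volume contains no container voxels")
    return n_fill / n_container


@dataclass(frozen=True)
class MassFvfResult:
    """FVF from the mass/density route, flagged when outside [0, 1]."""

    value: float
    grid_volume_ml: float
    in_range: bool

    def __float__(self) -> float:
        return self.value


def fvf_from_mass(m_grid_g: float, rho_g_per_cm3: float, v_no_grid_ml: float) -> MassFvfResult:
    """FVF = 1 - (m/rho) / V_container, emulating weighing of a printed grid.

    Out-of-range results (e.g. ``m/rho > V_container``) are returned unclipped
    with ``in_range=False`` and a warning, never silently clipped.
    """
    if m_grid_g < 0:
        raise InvalidParameterError("grid mass must be non-negative")
    if rho_g_per_cm3 <= 0 or v_no_grid_ml <= 0:
        raise InvalidParameterError("density and container volume must be positive")
    v_grid = m_grid_g / rho_g_per_cm3  # cm^3 == mL
    value = 1.0 - v_grid / v_no_grid_ml
    in_range = 0.0 <= value <= 1.0
    if not in_range:
        warnings.warn(
            f"mass-derived grid volume {v_grid:.3f} mL inconsistent with "
            f"container volume {v_no_grid_ml:.3f} mL (FVF = {value:.3f})",
            stacklevel=2,
        )
    return MassFvfResult(float(value), float(v_grid), in_range)


def delta_v(v_design_ml: float, v_measured_ml: float) -> float:
    """Signed relative volume deviation ``1 - V_design / V_measured``."""
    if v_measured_ml <= 0:
        raise InvalidParameterError("measured volume must be positive")
    return 1.0 - v_design_ml / v_measured_ml


# ---------------------------------------------------------------------------
# STL export
# ---------------------------------------------------------------------------


def _solid_mask(obj, voxel_size_mm: float):
    """Return (mask, voxel, origin) of the solid region of labels or a shape."""
    if isinstance(obj, VoxelVolume):
        return (obj.values == SOLID).astype(np.float32), obj.voxel_size_mm, obj.origin_mm
    if isinstance(obj, ContainerShape):
        from scipy.ndimage import gaussian_filter

        vol = rasterize_grid(None, obj, voxel_size_mm, pad_voxels=3)
        # light smoothing removes the staircase bias of a binary isosurface
        mask = gaussian_filter((vol.values == FILLABLE).astype(np.float32), 1.0)
        return mask, vol.voxel_size_mm, vol.origin_mm
    raise InvalidParameterError("expected a label VoxelVolume or a ContainerShape")


def export_stl(obj, path: str, voxel_size_mm: float = 1.0) -> int:
    """Write a binary STL of the solid-region isosurface; returns triangle count.

    For a :class:`ContainerShape` the container itself is meshed (treated as
    solid); for a label volume the SOLID voxels are meshed.  Marching cubes on
    a zero-padded binary mask yields a closed surface.
    """
    from skimage import measure

    mask, voxel, origin = _solid_mask(obj, voxel_size_mm)
    if not np.any(mask > 0.5):
        raise EmptyGeometryError("nothing to export: solid region is empty")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    # marching_cubes works in index space (z, y, x); map to world mm
    verts = (verts - 1.0) * np.asarray(voxel) + np.asarray(origin)
    verts_xyz = verts[:, ::-1]  # (x, y, z) for STL
    tris = verts_xyz[faces]
    write_binary_stl(path, tris)
    return len(faces)


def write_binary_stl(path: str, triangles: np.ndarray) -> None:
    """Write an (n, 3, 3) float array of triangles as little-endian binary STL."""
    tris = np.asarray(triangles, dtype=np.float32)
    n = tris.shape[0]
    normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norm, out=np.zeros_like(normals), where=norm > 0)
    rec = np.zeros(
        n,
        dtype=np.dtype(
            [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
        ),
    )
    rec["normal"] = normals
    rec["verts"] = tris
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 80)
        fh.write(struct.pack("<I", n))
        fh.write(rec.tobytes())


def read_binary_stl(path: str) -> np.ndarray:
    """Read a binary STL into an (n, 3, 3) float32 triangle array."""
    with open(path, "rb") as fh:
        fh.seek(80)
        (n,) = struct.unpack("<I", fh.read(4))
        rec = np.frombuffer(
            fh.read(n * 50),
            dtype=np.dtype(
                [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
            ),
        )
    return rec["verts"].copy()


def mesh_is_closed(triangles: np.ndarray) -> bool:
    """True iff every edge of the triangle soup is shared by exactly 2 faces."""
    tris = np.asarray(triangles)
    # quantize vertices so shared corners hash identically despite float noise
    verts = tris.reshape(-1, 3)
    keys = np.round(verts * 1e4).astype(np.int64)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    faces = inv.reshape(-1, 3)
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def mesh_surface_area(triangles: np.ndarray) -> float:
    tris = np.asarray(triangles, dtype=float)
    cross = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())
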