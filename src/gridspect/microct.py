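"""Synthetic micro-CT verification of printed grids.

Emulates the verification stage: synthesize a CT-like volume of a printed
grid with controllable printing defects, segment it (moment-preserving
threshold, 3x3x3 morphological cleaning, shell exclusion by an analytic
sphere fit), and quantify the grid volume and the spatial uniformity of
printing errors via central/peripheral void-area ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    EmptyGeometryError,
    FitError,
    InvalidParameterError,
    SamplingError,
)
from .gridgen import FILLABLE, OUTSIDE, SOLID, ContainerShape, GridSpec, rasterize_grid
from .projector import FWHM_TO_SIGMA
from .volume import VoxelVolume

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class DefectModel:
    """Printing-defect parameters injected into synthetic micro-CT volumes.

    ``edge_excess_mm`` deposits extra material around wall crossings (sharp
    edges); ``uniform_scale`` thickens every wall isotropically by that
    fraction of the wall thickness; ``blur_fwhm_mm`` and ``noise_sd`` model
    the scanner PSF and image noise.
    """

    edge_excess_mm: float = 0.0
    uniform_scale: float = 0.0
    noise_sd: float = 0.0
    blur_fwhm_mm: float = 0.0

    def __post_init__(self):
        if self.edge_excess_mm < 0 or self.blur_fwhm_mm < 0:
            raise InvalidParameterError("edge excess and blur must be >= 0")


def printed_grid_sphere_labels(
    spec: GridSpec | None,
    sphere_diameter_mm: float = 40.0,
    shell_thickness_mm: float = 2.0,
    voxel_size_mm: float = 0.1,
) -> VoxelVolume:
    """Label volume of a grid-filled sphere with its printed outer shell."""
    outer = ContainerShape.sphere(sphere_diameter_mm + 2 * shell_thickness_mm)
    labels = rasterize_grid(spec, outer, voxel_size_mm)
    zz, yy, xx = labels.coordinate_grids()
    r2 = zz**2 + yy**2 + xx**2
    shell = (r2 > (sphere_diameter_mm / 2.0) ** 2) & (labels.values != OUTSIDE)
    labels.values[shell] = SOLID
    labels.meta["shell_thickness_mm"] = shell_thickness_mm
    labels.meta["interior_diameter_mm"] = sphere_diameter_mm
    return labels


def _crossing_mask(labels: VoxelVolume, spec: GridSpec) -> np.ndarray:
    """Voxels lying inside walls of at least two wall families."""
    p = spec.period_mm
    count = np.zeros(labels.shape, dtype=np.int8)
    coords = labels.coordinate_grids()  # z, y, x world
    for ax in spec.wall_axes:
        i = _AXIS_INDEX[ax]
        c = coords[2 - i]  # world coordinate along that axis
        u = np.mod(c - spec.phase_mm[i], p)
        count += u < spec.wall_thickness_mm
    return count >= 2


def synth_microct(
    labels: VoxelVolume,
    defects: DefectModel,
    spec: GridSpec | None = None,
    seed: int = 0,
    solid_value: float = 1000.0,
    air_value: float = 0.0,
) -> VoxelVolume:
    """Two-level CT-like image of a printed grid with injected defects.

    Defects are applied to the solid mask (edge dilation at wall crossings,
    then global wall thickening), followed by Gaussian scanner blur and
    additive Gaussian noise.  Deterministic for a given seed.
    """
    voxel = labels.voxel_size_mm[0]
    if spec is not None and voxel > spec.wall_thickness_mm / 4.0 + 1e-12:
        raise SamplingError(
            f"wall under-resolved: need >= 4 voxels across a "
            f"{spec.wall_thickness_mm} mm wall at {voxel} mm voxels"
        )
    solid = labels.values == SOLID
    inside = labels.values != OUTSIDE

    if defects.edge_excess_mm > 0:
        if spec is None:
            raise InvalidParameterError("edge_excess defects require the grid spec")
        seeds = solid & _crossing_mask(labels, spec)
        if np.any(seeds):
            dist = ndimage.distance_transform_edt(
                ~seeds, sampling=labels.voxel_size_mm
            )
            solid = solid | ((dist <= defects.edge_excess_mm) & inside)
    if defects.uniform_scale > 0:
        if spec is None:
            raise InvalidParameterError("uniform_scale defects require the grid spec")
        # analytic symmetric thickening t -> t*(1+scale): exact at any voxel
        # size, unlike voxel-quantized morphological dilation
        dt = defects.uniform_scale * spec.wall_thickness_mm
        if dt >= spec.gap_mm:
            raise InvalidParameterError("thickening closes the grid gaps entirely")
        thick = GridSpec(
            spec.wall_thickness_mm + dt,
            spec.gap_mm - dt,
            spec.wall_axes,
            tuple(p - dt / 2.0 for p in spec.phase_mm),
        )
        pts = labels.points_xyz()
        walls = (~thick.fillable_points(pts)).reshape(labels.shape)
        solid = solid | (walls & inside)

    img = np.full(labels.shape, air_value, dtype=np.float64)
    img[solid] = solid_value
    if defects.blur_fwhm_mm > 0:
        sigma = defects.blur_fwhm_mm * FWHM_TO_SIGMA / voxel
        img = ndimage.gaussian_filter(img, sigma)
    if defects.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, defects.noise_sd, size=img.shape)
    return labels.copy(values=img, value_kind="hu", meta=dict(labels.meta))


def moment_preserving_threshold(image) -> float:
    """Threshold preserving the first three gray-level moments (Tsai).

    The bilevel representation (two levels z0 < z1, below-fraction p0) that
    matches moments m1..m3 is solved in closed form; the threshold is placed
    between the two sample values bracketing the p0-quantile, so an exact
    two-level image is split at the true fraction.
    """
    vals = np.asarray(
        image.values if isinstance(image, VoxelVolume) else image, dtype=float
    ).ravel()
    if not np.all(np.isfinite(vals)):
        raise InvalidParameterError("image values must be finite")
    m1 = vals.mean()
    if vals.size < 2 or np.ptp(vals) == 0:
        raise InvalidParameterError("degenerate histogram: zero variance")
    m2 = np.mean(vals**2)
    m3 = np.mean(vals**3)
    denom = m2 - m1 * m1
    if denom <= 0:
        raise InvalidParameterError("degenerate histogram: zero variance")
    c0 = (-m2 * m2 + m1 * m3) / denom
    c1 = (-m3 + m1 * m2) / denom
    disc = c1 * c1 - 4.0 * c0
    if disc <= 0:
        raise InvalidParameterError("moment system has no real bilevel solution")
    z0 = (-c1 - np.sqrt(disc)) / 2.0
    z1 = (-c1 + np.sqrt(disc)) / 2.0
    p0 = (z1 - m1) / (z1 - z0)
    p0 = min(max(p0, 0.0), 1.0)
    k = int(round(p0 * vals.size))
    k = min(max(k, 1), vals.size - 1)
    part = np.partition(vals, [k - 1, k])
    return float(0.5 * (part[k - 1] + part[k]))


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Morphological opening then closing with 3x3x3 structuring elements."""
    m = np.asarray(mask, dtype=bool)
    se = np.ones((3, 3, 3), dtype=bool)
    return ndimage.binary_closing(ndimage.binary_opening(m, se), se)


@dataclass
class ShellFit:
    center_mm: tuple[float, float, float]  # (x, y, z)
    radius_mm: float
    rms_mm: float


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def exclude_shell(
    mask: VoxelVolume | np.ndarray,
    voxel_size_mm: float | None = None,
    shell_thickness_mm: float = 2.0,
    n_directions: int = 600,
    return_fit: bool = False,
):
    """Remove the spherical container shell from a segmented grid mask.

    An analytic sphere is least-squares fitted to the outermost mask surface
    (the outer gradient maximum); voxels outside ``fitted radius - margin``
    are removed, with margin = shell thickness + 2 voxels.  Raises
    :class:`FitError` with the residual when the outer surface is not
    spherical (no shell present).
    """
    if isinstance(mask, VoxelVolume):
        vol = mask
        m = vol.values.astype(bool)
        voxel = vol.voxel_size_mm[0]
    else:
        if voxel_size_mm is None:
            raise InvalidParameterError("voxel size required for a bare array")
        m = np.asarray(mask, dtype=bool)
        voxel = float(voxel_size_mm)
        vol = None
    if not np.any(m):
        raise EmptyGeometryError("empty mask")

    idx = np.argwhere(m)
    centroid = idx.mean(axis=0)  # z, y, x voxel units
    dirs = _fibonacci_directions(n_directions)  # xyz
    rmax_vox = np.linalg.norm(np.array(m.shape))
    steps = np.arange(0.0, rmax_vox, 0.5)
    pts = []
    nz, ny, nx = m.shape
    for d in dirs:
        zz = centroid[0] + steps * d[2]
        yy = centroid[1] + steps * d[1]
        xx = centroid[2] + steps * d[0]
        ok = (zz >= 0) & (zz < nz) & (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
        hit = np.zeros(len(steps), dtype=bool)
        hit[ok] = m[
            zz[ok].astype(int), yy[ok].astype(int), xx[ok].astype(int)
        ]
        if hit.any():
            r = steps[np.nonzero(hit)[0][-1]]
            pts.append(centroid + r * d[::-1])
    pts = np.asarray(pts)
    if len(pts) < 10:
        raise FitError("too few surface points for a sphere fit")
    # linear least squares: |p|^2 = 2 p.c + (r^2 - |c|^2)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r_fit = np.sqrt(sol[3] + np.sum(center**2))
    resid = np.linalg.norm(pts - center, axis=1) - r_fit
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > max(3.0, 0.03 * r_fit):
        raise FitError(
            f"outer surface is not spherical (fit rms {rms * voxel:.2f} mm "
            f"for radius {r_fit * voxel:.2f} mm); no shell to exclude"
        )
    margin_vox = shell_thickness_mm / voxel + 2.0
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=True
    )
    r2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    interior = m & (r2 <= (r_fit - margin_vox) ** 2)
    fit = ShellFit(
        tuple((center[::-1] * voxel) if vol is None else _vox_to_world(vol, center)),
        float(r_fit * voxel),
        float(rms * voxel),
    )
    out = vol.copy(values=interior, value_kind="label") if vol is not None else interior
    if return_fit:
        return out, fit
    return out


def _vox_to_world(vol: VoxelVolume, center_zyx_vox) -> np.ndarray:
    w = np.asarray(vol.origin_mm) + np.asarray(center_zyx_vox) * np.asarray(
        vol.voxel_size_mm
    )
    return w[::-1]  # xyz


def grid_volume_from_ct(mask: VoxelVolume | np.ndarray, voxel_size_mm: float | None = None) -> float:
    """Solid grid volume in mL from a cleaned, shell-excluded mask."""
    if isinstance(mask, VoxelVolume):
        n = int(np.count_nonzero(mask.values))
        vv = mask.voxel_volume_ml
    else:
        if voxel_size_mm is None:
            raise InvalidParameterError("voxel size required for a bare array")
        n = int(np.count_nonzero(mask))
        vv = voxel_size_mm**3 / 1000.0
    if n == 0:
        warnings.warn("empty grid mask: volume is zero")
    return n * vv


def central_peripheral_ratio(
    solid_slice: np.ndarray,
    voxel_size_mm: float,
    interior_radius_mm: float,
    period_mm: float,
    center_yx_vox: tuple[float, float] | None = None,
    peripheral_radius_frac: float = 0.7,
    roi_side_periods: float = 3.0,
) -> float:
    """Central-to-peripheral void-fraction ratio on a transverse slice.

    Five central ROIs (plus-pattern) and four peripheral ROIs (diagonals at
    ``peripheral_radius_frac`` of the interior radius), each a square of
    ``roi_side_periods`` grid periods.  Void fractions are evaluated within
    the ROI clipped to the interior disc; for an ideally uniform grid the
    ratio is unity.

    ``roi_side_periods`` should be a whole number of periods and the ROIs
    should not overhang the interior disc: a window covering full periods has
    a phase-independent void fraction, so uniform (even defective-but-
    uniform) grids give exactly unity; fractional-period or clipped windows
    pick up the window phase instead.
    """
    m = np.asarray(solid_slice, dtype=bool)
    ny, nx = m.shape
    if center_yx_vox is None:
        center_yx_vox = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    cy, cx = center_yx_vox
    side = roi_side_periods * period_mm / voxel_size_mm
    r_int = interior_radius_mm / voxel_size_mm
    offsets_central = [(0, 0), (side, 0), (-side, 0), (0, side), (0, -side)]
    rp = peripheral_radius_frac * r_int / np.sqrt(2.0)
    offsets_periph = [(rp, rp), (rp, -rp), (-rp, rp), (-rp, -rp)]
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_int**2

    def void_fraction(dy, dx):
        y0, x0 = cy + dy, cx + dx
        if not (0 <= y0 < ny and 0 <= x0 < nx):
            raise InvalidParameterError("ROI center outside the slice")
        roi = (
            (np.abs(yy - y0) <= side / 2.0)
            & (np.abs(xx - x0) <= side / 2.0)
            & disc
        )
        n = int(np.count_nonzero(roi))
        if n == 0:
            raise InvalidParameterError("ROI lies outside the interior disc")
        return np.count_nonzero(roi & ~m) / n

    central = np.mean([void_fraction(*o) for o in offsets_central])
    periph = np.mean([void_fraction(*o) for o in offsets_periph])
    if periph == 0:
        raise InvalidParameterError("peripheral void area is zero")
    return float(central / periph)
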