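"""Quantitative image evaluation: modulation contrast, linear FVF fits,
activity recovery, threshold-volume curves, profiles and MIPs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import FitError, InvalidParameterError, ShapeMismatchError
from .volume import VoxelVolume


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    pearson_r: float
    slope_sd: float
    intercept_sd: float
    n_points: int


@dataclass
class ThresholdVolumeCurve:
    """Segmented volume as a function of an absolute concentration threshold,
    sampled at 100 equal steps of the image maximum."""

    thresholds: np.ndarray  # strictly increasing, same units as the image
    volumes_ml: np.ndarray  # non-increasing
    max_concentration: float

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.volumes_ml = np.asarray(self.volumes_ml, dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise InvalidParameterError("thresholds must be strictly increasing")
        if np.any(np.diff(self.volumes_ml) > 1e-9):
            raise InvalidParameterError("volumes must be non-increasing")


def sphere_voi_mask(
    image: VoxelVolume, center_xyz_mm, volume_ml: float
) -> np.ndarray:
    """Spherical VOI of a given physical volume centered at a known point."""
    if volume_ml <= 0:
        raise InvalidParameterError("VOI volume must be positive")
    r = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    zz, yy, xx = image.coordinate_grids()
    cx, cy, cz = center_xyz_mm
    return (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= r * r


def modulation_contrast(
    image: VoxelVolume, voi_grid: np.ndarray, voi_reference: np.ndarray
) -> float:
    """C_M = mean(grid VOI) / mean(reference VOI).

    Resolution-induced spill-out is assumed equal for the grid and reference
    objects, so it cancels in the ratio.
    """
    if not np.any(voi_grid) or not np.any(voi_reference):
        raise InvalidParameterError("VOIs must be non-empty")
    ref = float(image.values[voi_reference].mean())
    if ref == 0:
        raise InvalidParameterError("reference VOI mean is zero; contrast undefined")
    return float(image.values[voi_grid].mean() / ref)


def fit_cm_vs_fvf(points) -> FitResult:
    """Ordinary least squares of modulation contrast against FVF."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise FitError("need at least 3 (FVF, C_M) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) < 1e-12:
        raise FitError("degenerate FVF range")
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        slope_sd=float(res.stderr),
        intercept_sd=float(res.intercept_stderr),
        n_points=len(x),
    )


def recovery(image: VoxelVolume, voi: np.ndarray, true_activity_mbq: float) -> float:
    """R = (image-derived activity inside the VOI) / true activity.

    The image must be calibrated to MBq/mL.
    """
    if true_activity_mbq <= 0:
        raise InvalidParameterError("true activity must be positive")
    a_img = float(image.values[voi].sum() * image.voxel_volume_ml)
    return a_img / true_activity_mbq


def threshold_volume_curve(
    image: VoxelVolume, steps: int = 100, mask: np.ndarray | None = None
) -> ThresholdVolumeCurve:
    """Volume above threshold for thresholds at i/steps of the image maximum."""
    vals = np.asarray(image.values, dtype=float)
    if mask is not None:
        vals = np.where(mask, vals, 0.0)
    vmax = float(vals.max())
    if vmax <= 0:
        raise InvalidParameterError("image maximum must be positive")
    thresholds = vmax * np.arange(1, steps + 1) / steps
    flat = np.sort(vals.ravel())
    # volume(theta) = #{v >= theta} * voxel volume, via a sorted search
    counts = flat.size - np.searchsorted(flat, thresholds, side="left")
    volumes = counts * image.voxel_volume_ml
    return ThresholdVolumeCurve(thresholds, volumes, vmax)


def threshold_for_true_volume(curve: ThresholdVolumeCurve, v_true_ml: float) -> float:
    """Threshold (as a fraction of the image maximum) whose segmented volume
    equals the true volume, by linear interpolation along the curve."""
    if v_true_ml <= 0:
        raise InvalidParameterError("true volume must be positive")
    vols = curve.volumes_ml
    if v_true_ml > vols[0]:
        raise InvalidParameterError(
            f"true volume {v_true_ml} mL exceeds the volume at the lowest "
            f"threshold ({vols[0]} mL)"
        )
    # volumes are non-increasing with threshold: interpolate on reversed axes
    theta = np.interp(-v_true_ml, -vols, curve.thresholds)
    return float(theta / curve.max_concentration)


def mean_euclidean_distance(
    c1: ThresholdVolumeCurve, c2: ThresholdVolumeCurve
) -> float:
    """Mean absolute volume difference across corresponding curve samples."""
    if len(c1.volumes_ml) != len(c2.volumes_ml):
        raise ShapeMismatchError("curves sampled with a different number of steps")
    r1 = c1.thresholds / c1.max_concentration
    r2 = c2.thresholds / c2.max_concentration
    if not np.allclose(r1, r2, atol=1e-9):
        raise ShapeMismatchError("curves sampled at different relative thresholds")
    return float(np.mean(np.abs(c1.volumes_ml - c2.volumes_ml)))


def coronal_profile(
    image: VoxelVolume,
    line_index: int | None = None,
    n_slices: int = 3,
    slice_axis: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile along x after averaging the central coronal slices.

    Averages ``n_slices`` central slices along ``slice_axis`` (default y,
    the coronal stacking direction), then extracts the row at ``line_index``
    along z (default: central slice).  Returns (positions_mm, values).
    """
    if slice_axis not in (0, 1, 2):
        raise InvalidParameterError("slice axis out of range")
    n = image.shape[slice_axis]
    if n < n_slices:
        raise InvalidParameterError(
            f"image must be at least {n_slices} slices thick along the axis"
        )
    mid = n // 2
    lo = mid - n_slices // 2
    sl = [slice(None)] * 3
    sl[slice_axis] = slice(lo, lo + n_slices)
    mean2d = np.asarray(image.values)[tuple(sl)].mean(axis=slice_axis)
    # mean2d axes: remaining axes in order; for slice_axis=1 this is (z, x)
    if line_index is None:
        line_index = mean2d.shape[0] // 2
    profile = mean2d[line_index]
    positions = image.axis_coords(2 if slice_axis != 2 else 1)
    return positions, profile


def mip(image: VoxelVolume, axis: int = 1) -> np.ndarray:
    """Maximum-intensity projection along one axis."""
    if axis not in (0, 1, 2):
        raise InvalidParameterError("axis out of range")
    return np.asarray(image.values).max(axis=axis)
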