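"""Simplified rotation-based SPECT forward model.

The system operator for one projection angle is a composition of linear
steps, each implemented together with its exact adjoint so that the pair
(forward, backproject) is adjoint to floating-point precision:

1. in-plane rotation of the volume so the detector looks along +x
   (sparse bilinear-interpolation matrix; adjoint = transpose),
2. per-voxel attenuation toward the detector (diagonal; from the rotated
   attenuation map with a half-voxel self-attenuation offset),
3. per-slab Gaussian blur in the detector-parallel plane with a
   distance-dependent FWHM (symmetric zero-padded kernel; self-adjoint),
4. summation along the ray axis and scaling by
   sensitivity x time x voxel volume (adjoint = broadcast).

Primary photons only: scatter is neither simulated nor compensated, which is
equivalent to assuming a perfect scatter correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

from .errors import (
    ConfigError,
    GeometryError,
    InvalidParameterError,
    ShapeMismatchError,
)
from .volume import VoxelVolume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class Collimator:
    """Distance-dependent Gaussian collimator-detector response."""

    name: str
    intrinsic_fwhm_mm: float
    resolution_slope: float  # mm FWHM growth per mm distance
    sensitivity_cps_per_mbq: float

    def __post_init__(self):
        if self.intrinsic_fwhm_mm < 0 or self.resolution_slope < 0:
            raise InvalidParameterError("collimator response terms must be >= 0")
        if self.sensitivity_cps_per_mbq <= 0:
            raise InvalidParameterError("sensitivity must be positive")


def psf_fwhm(distance_mm: float, collimator: Collimator) -> float:
    """System FWHM at a source-to-collimator distance:
    ``sqrt(intrinsic^2 + (slope * distance)^2)``."""
    if np.any(np.asarray(distance_mm) < 0):
        raise InvalidParameterError("distance must be non-negative")
    return np.sqrt(
        collimator.intrinsic_fwhm_mm**2
        + (collimator.resolution_slope * np.asarray(distance_mm, dtype=float)) ** 2
    )


@dataclass(frozen=True)
class AcquisitionConfig:
    n_projections: int = 60
    arc_deg: float = 360.0
    matrix: int = 128
    pixel_size_mm: float = 4.42
    time_per_projection_s: float = 45.0
    orbit_radius_mm: float = 250.0
    collimator: Collimator = field(
        default_factory=lambda: Collimator("LEHR", 3.9, 0.0633, 90.0)
    )
    nuclide: str = "tc99m"
    mu_water_cm: float = 0.154

    def __post_init__(self):
        if self.n_projections < 1:
            raise ConfigError("need at least one projection")
        if self.pixel_size_mm <= 0 or self.time_per_projection_s <= 0:
            raise ConfigError("pixel size and time per projection must be positive")
        if self.orbit_radius_mm <= 0:
            raise ConfigError("orbit radius must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return self.arc_deg * np.arange(self.n_projections) / self.n_projections


@dataclass
class ProjectionSet:
    """Per-angle 2D count arrays, shape (n_angles, n_rows_z, n_cols_u)."""

    counts: np.ndarray
    angles_deg: np.ndarray
    kind: str  # 'expected' | 'noisy'
    acquisition: AcquisitionConfig
    voxel_size_mm: float
    rng_seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise InvalidParameterError("counts must be (angles, rows, cols)")
        if self.counts.shape[0] != len(self.angles_deg):
            raise ShapeMismatchError("counts/angles mismatch")
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        if self.kind not in ("expected", "noisy"):
            raise InvalidParameterError("kind must be 'expected' or 'noisy'")

    def total_counts(self) -> float:
        return float(self.counts.sum())


# ---------------------------------------------------------------------------
# Rotation operator cache
# ---------------------------------------------------------------------------

_ROT_CACHE: dict[tuple, sparse.csr_matrix] = {}


def _rotation_operator(ny: int, nx: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse bilinear rotation of an (ny, nx) image about its center.

    Row = output pixel; the output pixel samples the input at the position
    obtained by rotating its own coordinates by ``angle_deg``.  The exact
    backprojection rotation is the transpose of this matrix.
    """
    key = (ny, nx, round(float(angle_deg) % 360.0, 9))
    hit = _ROT_CACHE.get(key)
    if hit is not None:
        return hit
    th = np.deg2rad(angle_deg)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    oy, ox = np.meshgrid(np.arange(ny) - cy, np.arange(nx) - cx, indexing="ij")
    src_x = cx + np.cos(th) * ox + np.sin(th) * oy
    src_y = cy - np.sin(th) * ox + np.cos(th) * oy
    x0 = np.floor(src_x)
    y0 = np.floor(src_y)
    wx = src_x - x0
    wy = src_y - y0
    rows, cols, data = [], [], []
    out_idx = np.arange(ny * nx)
    for dy, dx, w in (
        (0, 0, (1 - wy) * (1 - wx)),
        (0, 1, (1 - wy) * wx),
        (1, 0, wy * (1 - wx)),
        (1, 1, wy * wx),
    ):
        yy = (y0 + dy).astype(np.int64)
        xx = (x0 + dx).astype(np.int64)
        valid = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx) & (w.ravel() > 0).reshape(yy.shape)
        rows.append(out_idx[valid.ravel()])
        cols.append((yy * nx + xx)[valid])
        data.append(w[valid])
    mat = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nx, ny * nx),
    )
    _ROT_CACHE[key] = mat
    return mat


# ---------------------------------------------------------------------------
# System model
# ---------------------------------------------------------------------------


class SystemModel:
    """Linear SPECT system operator for a fixed attenuation map and geometry.

    ``include_psf`` toggles the distance-dependent collimator response; the
    attenuation model is always applied.  ``forward``/``adjoint`` are exact
    adjoints of each other.
    """

    def __init__(
        self,
        mu: VoxelVolume,
        acq: AcquisitionConfig,
        include_psf: bool = True,
        sigma_quant_vox: float = 0.05,
        cache_attenuation: bool = True,
        include_sensitivity: bool = True,
    ):
        if mu.values.ndim != 3:
            raise ShapeMismatchError("attenuation map must be 3D")
        vz, vy, vx = mu.voxel_size_mm
        if not (abs(vz - vy) < 1e-9 and abs(vy - vx) < 1e-9):
            raise ConfigError("system model requires isotropic voxels")
        self.mu = mu
        self.acq = acq
        self.include_psf = include_psf
        self.voxel_mm = float(vx)
        self.shape = mu.values.shape
        nz, ny, nx = self.shape
        # the orbit must clear the attenuating object (not the padded lattice)
        inplane = mu.values.any(axis=0)
        if inplane.any():
            iy, ix = np.nonzero(inplane)
            ry = (iy - (ny - 1) / 2.0) * self.voxel_mm
            rx = (ix - (nx - 1) / 2.0) * self.voxel_mm
            r_obj = float(np.hypot(ry, rx).max())
            if acq.orbit_radius_mm < r_obj:
                raise GeometryError(
                    f"orbit radius {acq.orbit_radius_mm} mm inside the object "
                    f"(in-plane radius {r_obj:.1f} mm)"
                )
        self.angles = acq.angles_deg
        # distance of each rotated x-slab to the collimator face; empty lattice
        # corners may lie beyond the collimator plane -> clamp at contact
        xs = (np.arange(nx) - (nx - 1) / 2.0) * self.voxel_mm
        dist = np.maximum(acq.orbit_radius_mm - xs, 0.0)
        fwhm = psf_fwhm(dist, acq.collimator)
        sig = fwhm * FWHM_TO_SIGMA / self.voxel_mm
        if include_psf:
            sig_q = np.round(sig / sigma_quant_vox) * sigma_quant_vox
        else:
            sig_q = np.zeros_like(sig)
        self._sigma = sig_q
        self._sigma_groups = [
            (s, np.nonzero(sig_q == s)[0]) for s in np.unique(sig_q)
        ]
        # absolute system sensitivity enters the simulation model but not the
        # reconstruction model: like a real off-line reconstruction, absolute
        # counts-per-activity scaling is left to the image calibration factor
        self.scale = acq.time_per_projection_s * (self.voxel_mm**3 / 1000.0)
        if include_sensitivity:
            self.scale *= acq.collimator.sensitivity_cps_per_mbq
        self._att_cache: dict[int, np.ndarray] = {}
        self._cache_att = cache_attenuation

    # -- per-angle pieces ---------------------------------------------------
    #
    # The forward rotation is the *transpose* of a bilinear gather operator
    # (i.e. splatting): every input voxel distributes exactly unit weight, so
    # projection counts are conserved; the backprojection rotation is the
    # gather itself, keeping the forward/adjoint pair exact.

    def _gather(self, iangle: int) -> sparse.csr_matrix:
        return _rotation_operator(self.shape[1], self.shape[2], -self.angles[iangle])

    def _rotate_fwd(self, vol: np.ndarray, iangle: int) -> np.ndarray:
        nz, ny, nx = self.shape
        g = self._gather(iangle)
        return (g.T @ vol.reshape(nz, ny * nx).T).T.reshape(nz, ny, nx)

    def _rotate_adj(self, vol: np.ndarray, iangle: int) -> np.ndarray:
        nz, ny, nx = self.shape
        g = self._gather(iangle)
        return (g @ vol.reshape(nz, ny * nx).T).T.reshape(nz, ny, nx)

    def _attenuation(self, iangle: int) -> np.ndarray:
        att = self._att_cache.get(iangle)
        if att is not None:
            return att
        nz, ny, nx = self.shape
        mu_rot = self._rotate_fwd(self.mu.values.astype(float), iangle)
        dx_cm = self.voxel_mm / 10.0
        # path integral from each voxel to the detector at +x, half-voxel
        # self-attenuation offset
        csum = np.cumsum(mu_rot[:, :, ::-1], axis=2)[:, :, ::-1]
        att = np.exp(-(csum - 0.5 * mu_rot) * dx_cm).astype(np.float32)
        if self._cache_att:
            self._att_cache[iangle] = att
        return att

    def _blur(self, vol: np.ndarray) -> np.ndarray:
        """Distance-dependent (z, y) blur of a rotated volume, in place-safe."""
        if not self.include_psf:
            return vol
        out = vol
        for s, idx in self._sigma_groups:
            if s <= 1e-9 or idx.size == 0:
                continue
            sub = out[:, :, idx]
            sub = gaussian_filter(sub, sigma=(s, s, 0.0), mode="constant")
            out[:, :, idx] = sub
        return out

    # -- forward / adjoint --------------------------------------------------

    def forward_angle(self, x: np.ndarray, iangle: int) -> np.ndarray:
        xr = self._rotate_fwd(np.asarray(x, dtype=float), iangle)
        xr = xr * self._attenuation(iangle)
        xr = self._blur(xr)
        return xr.sum(axis=2) * self.scale

    def adjoint_angle(self, proj: np.ndarray, iangle: int) -> np.ndarray:
        nx = self.shape[2]
        vol = np.repeat(proj[:, :, None] * self.scale, nx, axis=2)
        vol = self._blur(vol)
        vol = vol * self._attenuation(iangle)
        return self._rotate_adj(vol, iangle)

    def forward_subset(self, x: np.ndarray, idx) -> np.ndarray:
        return np.stack([self.forward_angle(x, i) for i in idx])

    def adjoint_subset(self, projs: np.ndarray, idx) -> np.ndarray:
        out = np.zeros(self.shape)
        for p, i in zip(projs, idx):
            out += self.adjoint_angle(p, i)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.forward_subset(x, range(len(self.angles)))

    def adjoint(self, projs: np.ndarray) -> np.ndarray:
        return self.adjoint_subset(projs, range(len(self.angles)))


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def forward_project(
    activity: VoxelVolume,
    mu: VoxelVolume,
    acq: AcquisitionConfig,
    include_psf: bool = True,
) -> ProjectionSet:
    """Noiseless expected projections of an activity map (MBq/mL)."""
    if activity.values.shape != mu.values.shape or not np.allclose(
        activity.voxel_size_mm, mu.voxel_size_mm
    ):
        raise ShapeMismatchError("activity and attenuation lattices differ")
    model = SystemModel(mu, acq, include_psf=include_psf, cache_attenuation=False)
    counts = model.forward(np.asarray(activity.values, dtype=float))
    return ProjectionSet(
        counts, acq.angles_deg, "expected", acq, float(activity.voxel_size_mm[0])
    )


def rebin_projections(projs: ProjectionSet, factor: int) -> ProjectionSet:
    """Sum ``factor x factor`` blocks of detector bins (counts are additive).

    Used when the forward simulation ran on a lattice ``factor`` times finer
    than the acquisition pixel size: sub-pixel structure is then resolved and
    blurred by the PSF *before* detector sampling, instead of aliasing into a
    moire pattern at voxelization.
    """
    f = int(factor)
    n, nz, ny = projs.counts.shape
    if nz % f or ny % f:
        raise ShapeMismatchError("projection bins not divisible by rebin factor")
    c = projs.counts.reshape(n, nz // f, f, ny // f, f).sum(axis=(2, 4))
    return replace(projs, counts=c, voxel_size_mm=projs.voxel_size_mm * f)


def add_poisson(expected: ProjectionSet, seed: int) -> ProjectionSet:
    """Independent Poisson draws per bin; deterministic for a given seed."""
    if expected.kind != "expected":
        raise InvalidParameterError("input must be an expected-count projection set")
    if not np.all(np.isfinite(expected.counts)) or np.any(expected.counts < 0):
        raise InvalidParameterError("expected counts must be finite and >= 0")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(expected.counts).astype(np.int64)
    return replace(expected, counts=noisy, kind="noisy", rng_seed=int(seed))


def simulate_calibration(
    acq: AcquisitionConfig,
    recon_cfg,
    cylinder_diameter_mm: float = 216.0,
    cylinder_height_mm: float = 120.0,
    concentration_mbq_per_ml: float = 0.1,
    voxel_size_mm: float = 4.42,
) -> float:
    """Image calibration factor from a simulated uniform cylinder.

    The cylinder is forward-projected noiselessly and reconstructed with the
    supplied settings; the factor is the mean reconstructed value inside a
    centrally eroded VOI divided by the true concentration.  Dividing a
    reconstruction by this factor yields MBq/mL.
    """
    from .phantoms import ContainerShape, occupancy
    from .recon import gaussian_postfilter, osem_reconstruct
    from .volume import centered_grid

    if concentration_mbq_per_ml <= 0:
        raise InvalidParameterError("calibration activity must be positive")
    n_inplane = int(np.ceil((cylinder_diameter_mm + 30.0) / voxel_size_mm))
    nz = int(np.ceil(cylinder_height_mm / voxel_size_mm)) + 4
    grid = centered_grid((nz, n_inplane, n_inplane), voxel_size_mm, "activity")
    cyl = ContainerShape.cylinder(cylinder_diameter_mm, cylinder_height_mm)
    occ = occupancy(grid, cyl.contains, None, 2)
    act = grid.copy(values=occ * concentration_mbq_per_ml)
    mu = grid.copy(values=occ * acq.mu_water_cm, value_kind="attenuation")
    projs = forward_project(act, mu, acq)
    recon = osem_reconstruct(projs, mu, recon_cfg)
    if recon_cfg.post_filter_fwhm_mm:
        recon = gaussian_postfilter(recon, recon_cfg.post_filter_fwhm_mm)
    # central VOI: half radius, central half height
    zz, yy, xx = recon.coordinate_grids()
    voi = (
        (yy**2 + xx**2 <= (cylinder_diameter_mm / 4.0) ** 2)
        & (np.abs(zz) <= cylinder_height_mm / 4.0)
    )
    factor = float(recon.values[voi].mean() / concentration_mbq_per_ml)
    if factor <= 0:
        raise InvalidParameterError("degenerate calibration factor")
    return factor
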