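"""Digital phantom assembly: grid spheres, kidneys, thyroids.

Phantoms are described as ordered lists of *painters* — mutually exclusive
point-membership regions tied to compartments — plus a surrounding water
cylinder.  Maps are produced on a coarse (SPECT) lattice by supersampling the
membership predicates, so sub-voxel grid structure is represented as
fractional occupancy exactly as finite detector resolution would average it.

Two modes mirror the two experimental routes:

* ``grid_resolved`` — the grid walls are explicit geometry (digital twin of a
  printed phantom);
* ``compartment_averaged`` — grid regions carry the volume-averaged
  concentration ``FVF * c`` (digital twin of the simulation setup).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import GeometryError, InvalidParameterError, SamplingError
from .gridgen import ContainerShape, GridSpec, solve_wall_for_fvf
from .volume import VoxelVolume, centered_grid

RESIN_DENSITY_G_PER_CM3 = 1.192
WATER_DENSITY_G_PER_CM3 = 1.0

# narrow-beam water attenuation at the photopeaks (1/cm)
MU_WATER_CM = {"tc99m": 0.154, "lu177": 0.137}

Region = Callable[[np.ndarray], np.ndarray]  # (N,3) xyz mm -> bool


@dataclass
class Compartment:
    """A labeled phantom region with uniform activity and material."""

    id: int
    name: str
    activity_concentration: float  # MBq/mL
    density: float = WATER_DENSITY_G_PER_CM3
    mu_override: float | None = None
    solid_fraction: float = 0.0  # fraction of the region occupied by resin

    def __post_init__(self):
        if self.activity_concentration < 0:
            raise InvalidParameterError("activity concentration must be >= 0")
        if self.solid_fraction >= 1.0 and self.activity_concentration > 0:
            raise InvalidParameterError("fully solid compartments carry no activity")


@dataclass
class Painter:
    """A region of space painted with one compartment's properties.

    ``fill_weight`` is the fillable fraction of the region (1 for open
    liquid, the FVF for averaged grid regions, 0 for solid material); it is
    used to measure the realized fillable volume of a phantom.
    """

    compartment_id: int
    region: Region
    bbox_mm: tuple[np.ndarray, np.ndarray]  # (lo_xyz, hi_xyz)
    min_feature_mm: float | None = None  # smallest structure to resolve
    fill_weight: float = 0.0


@dataclass
class PhantomModel:
    """Compartmentalized phantom inside a background water cylinder."""

    compartments: list[Compartment]
    painters: list[Painter]
    cylinder: ContainerShape
    mode: str
    fillable_volume_ml: float
    total_activity_mbq: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("grid_resolved", "compartment_averaged"):
            raise InvalidParameterError(f"unknown phantom mode {self.mode!r}")
        ids = {c.id for c in self.compartments}
        for p in self.painters:
            if p.compartment_id not in ids:
                raise InvalidParameterError("painter references unknown compartment")

    def compartment(self, cid: int) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def bbox_mm(self) -> tuple[np.ndarray, np.ndarray]:
        los = np.array([p.bbox_mm[0] for p in self.painters])
        his = np.array([p.bbox_mm[1] for p in self.painters])
        return los.min(axis=0), his.max(axis=0)

    def labels(self, voxel_size_mm: float = 1.0) -> VoxelVolume:
        """Voxel-center compartment labels over the phantom bounding box."""
        lo, hi = self.bbox_mm()
        shape_xyz = np.maximum(np.ceil((hi - lo) / voxel_size_mm).astype(int), 1)
        origin = tuple((lo + voxel_size_mm / 2.0)[::-1])  # zyx
        vol = VoxelVolume(
            np.zeros((shape_xyz[2], shape_xyz[1], shape_xyz[0]), dtype=np.int16),
            voxel_size_mm,
            origin,
            "label",
        )
        pts = vol.points_xyz()
        lab = vol.values.reshape(-1)
        for p in self.painters:
            lab[p.region(pts)] = p.compartment_id
        return vol


# ---------------------------------------------------------------------------
# Region algebra
# ---------------------------------------------------------------------------


def _intersect(*regions: Region) -> Region:
    def pred(pts):
        out = regions[0](pts)
        for r in regions[1:]:
            out = out & r(pts)
        return out

    return pred


def _subtract(region: Region, *minus: Region) -> Region:
    def pred(pts):
        out = region(pts).copy()
        for r in minus:
            out &= ~r(pts)
        return out

    return pred


def _union(*regions: Region) -> Region:
    def pred(pts):
        out = regions[0](pts)
        for r in regions[1:]:
            out = out | r(pts)
        return out

    return pred


def _ellipsoid(center_xyz, semi_xyz) -> Region:
    c = np.asarray(center_xyz, dtype=float)
    s = np.asarray(semi_xyz, dtype=float)

    def pred(pts):
        q = (np.asarray(pts) - c) / s
        return np.sum(q * q, axis=1) <= 1.0

    return pred


def _sphere(center_xyz, diameter_mm) -> Region:
    return _ellipsoid(center_xyz, (diameter_mm / 2.0,) * 3)


# ---------------------------------------------------------------------------
# Occupancy painting
# ---------------------------------------------------------------------------


def occupancy(
    template: VoxelVolume,
    region: Region,
    bbox_mm: tuple[np.ndarray, np.ndarray] | None = None,
    supersample: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Per-voxel occupied fraction of ``region`` on the template lattice.

    Each voxel is probed with ``supersample**3`` stratified sub-points, one
    uniform random point per subcell (deterministic for a given seed).  The
    jitter breaks aliasing between the sampling lattice and periodic grid
    structure, making the estimate unbiased; regular sampling is biased by
    several percent when the grid period nearly matches the voxel pitch.
    Only voxels intersecting ``bbox_mm`` (xyz) are evaluated.
    """
    s = int(supersample)
    rng = np.random.default_rng(seed)
    out = np.zeros(template.shape, dtype=np.float64)
    vz, vy, vx = template.voxel_size_mm
    zc, yc, xc = (template.axis_coords(a) for a in range(3))
    if bbox_mm is not None:
        lo, hi = (np.asarray(b, dtype=float) for b in bbox_mm)
        iz = np.nonzero((zc > lo[2] - vz) & (zc < hi[2] + vz))[0]
        iy = np.nonzero((yc > lo[1] - vy) & (yc < hi[1] + vy))[0]
        ix = np.nonzero((xc > lo[0] - vx) & (xc < hi[0] + vx))[0]
        if len(iz) == 0 or len(iy) == 0 or len(ix) == 0:
            return out
        z0, z1 = iz[0], iz[-1] + 1
        y0, y1 = iy[0], iy[-1] + 1
        x0, x1 = ix[0], ix[-1] + 1
    else:
        z0, z1, y0, y1, x0, x1 = 0, len(zc), 0, len(yc), 0, len(xc)

    def strata(coords, v):
        # subcell left edges for every voxel along one axis
        off = (np.arange(s) / s - 0.5) * v
        return (coords[:, None] + off[None, :]).reshape(-1)

    ys = strata(yc[y0:y1], vy)
    xs = strata(xc[x0:x1], vx)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    base_xy = np.column_stack([xx.ravel(), yy.ravel()])
    zbase = (np.arange(s) / s - 0.5) * vz
    npts = base_xy.shape[0]
    pts = np.empty((npts, 3))
    for k, z in enumerate(zc[z0:z1]):
        acc = np.zeros(((y1 - y0), (x1 - x0)))
        for dz in zbase:
            pts[:, 0] = base_xy[:, 0] + rng.random(npts) * (vx / s)
            pts[:, 1] = base_xy[:, 1] + rng.random(npts) * (vy / s)
            pts[:, 2] = z + dz + rng.random(npts) * (vz / s)
            m = region(pts).reshape(y1 - y0, s, x1 - x0, s)
            acc += m.mean(axis=(1, 3))
        out[z0 + k, y0:y1, x0:x1] = acc / s
    return out


def assemble_maps(
    phantom: PhantomModel,
    voxel_size_mm: float = 4.42,
    medium: str = "water",
    mu_water_cm: float = MU_WATER_CM["tc99m"],
    grid_shape: tuple[int, int, int] | None = None,
    supersample: int | None = None,
    axial_margin_mm: float = 40.0,
    inplane_margin_mm: float = 30.0,
) -> tuple[VoxelVolume, VoxelVolume]:
    """Voxelize a phantom into (activity MBq/mL, attenuation 1/cm) maps.

    ``medium='water'`` assigns the water attenuation coefficient everywhere
    inside the background cylinder; ``medium='resin_aware'`` additionally
    scales the coefficient by the resin/water density ratio in proportion to
    the per-voxel solid occupancy.
    """
    if medium not in ("water", "resin_aware"):
        raise InvalidParameterError(f"unknown medium {medium!r}")
    # sampling adequacy for grid-resolved structure
    feats = [p.min_feature_mm for p in phantom.painters if p.min_feature_mm]
    if supersample is None:
        supersample = 4
        if feats:
            need = min(feats) / 2.0
            supersample = max(4, int(math.ceil(voxel_size_mm / need)) + 1)
    if feats and voxel_size_mm / supersample > min(feats) / 2.0 + 1e-12:
        raise SamplingError(
            f"supersample={supersample} at {voxel_size_mm} mm voxels cannot "
            f"resolve {min(feats)} mm grid features"
        )

    cyl = phantom.cylinder
    if grid_shape is None:
        d = cyl.params["diameter_mm"]
        n_inplane = int(math.ceil((d + inplane_margin_mm) / voxel_size_mm))
        lo, hi = phantom.bbox_mm()
        nz = int(math.ceil((hi[2] - lo[2] + 2 * axial_margin_mm) / voxel_size_mm))
        grid_shape = (nz, n_inplane, n_inplane)
    act = centered_grid(grid_shape, voxel_size_mm, "activity")
    lo, hi = phantom.bbox_mm()
    # phantom must fit inside the lattice
    half = np.array(
        [act.shape[2] * voxel_size_mm / 2, act.shape[1] * voxel_size_mm / 2,
         act.shape[0] * voxel_size_mm / 2]
    )
    if np.any(lo < -half - 1e-9) or np.any(hi > half + 1e-9):
        raise GeometryError("phantom extends beyond the requested lattice")

    solid_occ = np.zeros(act.shape)
    for p in phantom.painters:
        comp = phantom.compartment(p.compartment_id)
        if comp.activity_concentration == 0 and comp.solid_fraction == 0:
            continue
        occ = occupancy(act, p.region, p.bbox_mm, supersample)
        if comp.activity_concentration > 0:
            act.values += occ * comp.activity_concentration
        if comp.solid_fraction > 0:
            solid_occ += occ * comp.solid_fraction

    cyl_occ = occupancy(act, cyl.contains, None, 2)
    mu = act.copy(values=cyl_occ * mu_water_cm, value_kind="attenuation")
    if medium == "resin_aware":
        ratio = RESIN_DENSITY_G_PER_CM3 / WATER_DENSITY_G_PER_CM3
        mu.values += solid_occ * mu_water_cm * (ratio - 1.0)
    act.meta["total_activity_mbq"] = float(act.values.sum() * act.voxel_volume_ml)
    act.meta["mode"] = phantom.mode
    return act, mu


# ---------------------------------------------------------------------------
# Sphere phantoms
# ---------------------------------------------------------------------------

_SHELL_MM = 1.5  # printed container wall thickness (non-radioactive)


def _grid_painters(
    region: Region,
    bbox,
    fvf: float,
    concentration: float,
    mode: str,
    comp_fill: Compartment,
    comp_solid: Compartment | None,
    comp_avg: Compartment | None,
    grid_period_mm: float,
    phase_center=(0.0, 0.0, 0.0),
):
    """Painters for a grid-filled region in either mode; returns (painters, spec)."""
    if not 0 < fvf <= 1:
        raise InvalidParameterError("FVF must lie in (0, 1]")
    if fvf == 1.0:
        comp_fill.activity_concentration = concentration
        return [Painter(comp_fill.id, region, bbox, fill_weight=1.0)], None
    spec = solve_wall_for_fvf(fvf, grid_period_mm)
    # center a gap on the region center so the pattern is symmetric
    c = np.asarray(phase_center, dtype=float)
    phase = tuple(c - (spec.wall_thickness_mm + spec.period_mm) / 2.0)
    spec = GridSpec(spec.wall_thickness_mm, spec.gap_mm, spec.wall_axes, phase)
    minfeat = min(spec.wall_thickness_mm, spec.gap_mm)
    if mode == "grid_resolved":
        fill = _intersect(region, spec.fillable_points)
        solid = _intersect(region, lambda pts: ~spec.fillable_points(pts))
        comp_fill.activity_concentration = concentration
        return (
            [
                Painter(comp_fill.id, fill, bbox, minfeat, fill_weight=1.0),
                Painter(comp_solid.id, solid, bbox, minfeat),
            ],
            spec,
        )
    comp_avg.activity_concentration = fvf * concentration
    comp_avg.solid_fraction = 1.0 - fvf
    return [Painter(comp_avg.id, region, bbox, fill_weight=fvf)], spec


def measure_fillable_volume(
    painters: Sequence[Painter],
    probe_voxel_mm: float = 1.5,
    supersample: int = 3,
    seed: int = 0,
) -> float:
    """Realized fillable volume (mL) of a painter set by stratified sampling.

    This is the digital analogue of determining the printed grid volume by
    weighing: the realized geometry, not the design formula, is measured.
    """
    total = 0.0
    for p in painters:
        if p.fill_weight <= 0:
            continue
        lo, hi = (np.asarray(b, dtype=float) for b in p.bbox_mm)
        shape = np.maximum(np.ceil((hi - lo)[::-1] / probe_voxel_mm).astype(int) + 2, 1)
        probe = VoxelVolume(
            np.zeros(shape), probe_voxel_mm,
            tuple((lo - probe_voxel_mm / 2.0)[::-1]), "label",
        )
        occ = occupancy(probe, p.region, (lo, hi), supersample, seed)
        total += p.fill_weight * float(occ.sum()) * probe.voxel_volume_ml
    return total


def build_sphere_phantom(
    fvf_list: Sequence[float],
    sphere_diameter_mm: float = 40.0,
    cylinder_mm: tuple[float, float] = (216.0, 186.0),
    concentration_mbq_per_ml: float = 3.02,
    grid_period_mm: float = 3.2,
    mode: str = "grid_resolved",
    positions=None,
) -> list[PhantomModel]:
    """One phantom per FVF: a grid-filled sphere in a Jaszczak-type cylinder.

    ``FVF = 1`` yields the grid-free reference sphere.  ``positions`` places
    sphere centers (xyz mm); default is the cylinder axis.
    """
    return [
        build_sphere_set_phantom(
            [fvf],
            sphere_diameter_mm,
            cylinder_mm,
            concentration_mbq_per_ml,
            grid_period_mm,
            mode,
            positions=[positions[i] if positions is not None else (0.0, 0.0, 0.0)],
        )
        for i, fvf in enumerate(fvf_list)
    ]


def build_sphere_set_phantom(
    fvf_list: Sequence[float],
    sphere_diameter_mm: float = 40.0,
    cylinder_mm: tuple[float, float] = (216.0, 186.0),
    concentration_mbq_per_ml: float = 3.02,
    grid_period_mm: float = 3.2,
    mode: str = "grid_resolved",
    ring_radius_mm: float | None = 60.0,
    positions=None,
) -> PhantomModel:
    """All spheres mounted together in one cylinder (single acquisition).

    Default placement is a ring of radius ``ring_radius_mm`` in the central
    transverse plane; a single sphere goes on the axis.
    """
    fvfs = list(fvf_list)
    d_cyl, h_cyl = cylinder_mm
    cyl = ContainerShape.cylinder(d_cyl, h_cyl)
    r_sph = sphere_diameter_mm / 2.0
    if positions is None:
        if len(fvfs) == 1:
            positions = [(0.0, 0.0, 0.0)]
        elif len(fvfs) <= 5:
            # snap centers to voxel-congruent positions (axes + center) so
            # discretized VOIs are congruent and alignment bias cancels in
            # VOI-mean ratios; 13 voxels = 57.46 mm at the 4.42 mm grid
            r = 13 * 4.42
            axis_pos = [(r, 0.0, 0.0), (-r, 0.0, 0.0), (0.0, r, 0.0), (0.0, -r, 0.0)]
            positions = axis_pos[: len(fvfs) - 1] + [(0.0, 0.0, 0.0)]
        else:
            ang = 2 * np.pi * np.arange(len(fvfs)) / len(fvfs) + np.pi / 2
            positions = [
                (ring_radius_mm * np.cos(a), ring_radius_mm * np.sin(a), 0.0)
                for a in ang
            ]
    for pos in positions:
        if np.hypot(pos[0], pos[1]) + r_sph + _SHELL_MM > d_cyl / 2.0 or abs(
            pos[2]
        ) + r_sph + _SHELL_MM > h_cyl / 2.0:
            raise GeometryError(f"sphere at {pos} does not fit inside the cylinder")

    v_sphere = 4.0 / 3.0 * np.pi * r_sph**3 / 1000.0
    compartments, painters, spheres_meta = [], [], []
    next_id = 1
    fillable_total = 0.0
    for fvf, pos in zip(fvfs, positions):
        c = np.asarray(pos, dtype=float)
        interior = _sphere(c, sphere_diameter_mm)
        bbox = (c - r_sph, c + r_sph)
        comp_fill = Compartment(next_id, "sphere_interior", 0.0)
        comp_solid = Compartment(next_id + 1, "grid_solid", 0.0,
                                 RESIN_DENSITY_G_PER_CM3, solid_fraction=1.0)
        comp_avg = Compartment(next_id + 2, "sphere_averaged", 0.0)
        ps, spec = _grid_painters(
            interior, bbox, fvf, concentration_mbq_per_ml, mode,
            comp_fill, comp_solid, comp_avg, grid_period_mm, c,
        )
        painters.extend(ps)
        fillable_sphere = measure_fillable_volume(ps)
        used = {p.compartment_id for p in ps}
        compartments.extend(
            cmp for cmp in (comp_fill, comp_solid, comp_avg) if cmp.id in used
        )
        # non-radioactive printed shell
        shell = _subtract(_sphere(c, sphere_diameter_mm + 2 * _SHELL_MM), interior)
        comp_shell = Compartment(next_id + 3, "wall", 0.0, RESIN_DENSITY_G_PER_CM3,
                                 solid_fraction=1.0)
        compartments.append(comp_shell)
        painters.append(
            Painter(comp_shell.id, shell,
                    (c - r_sph - _SHELL_MM, c + r_sph + _SHELL_MM))
        )
        spheres_meta.append(
            {"center_mm": tuple(c), "fvf": fvf,
             "fvf_realized": fillable_sphere / v_sphere,
             "diameter_mm": sphere_diameter_mm,
             "volume_ml": v_sphere, "fillable_ml": fillable_sphere, "grid": spec}
        )
        fillable_total += fillable_sphere
        next_id += 4

    total = concentration_mbq_per_ml * fillable_total
    return PhantomModel(
        compartments, painters, cyl, mode, fillable_total, total,
        {"spheres": spheres_meta, "concentration_mbq_per_ml": concentration_mbq_per_ml},
    )


# ---------------------------------------------------------------------------
# Kidney phantom
# ---------------------------------------------------------------------------


def _ellipsoid_cap_u(volume_fraction: float) -> float:
    """Normalized plane offset u0 such that the ellipsoid cap beyond the plane
    holds the given volume fraction (cap fraction = (2 - 3u + u^3)/4)."""

    def frac(u):
        return (2.0 - 3.0 * u + u**3) / 4.0 - volume_fraction

    return brentq(frac, -1.0, 1.0)


def build_kidney_phantom(
    fillable_volume_ml: float = 116.0,
    medulla_fvf: float = 0.36,
    cortex_concentration: float | None = None,
    mode: str = "compartment_averaged",
    total_activity_mbq: float | None = None,
    cylinder_mm: tuple[float, float] = (216.0, 186.0),
    pelvis_fraction: float = 0.055,
    medulla_fraction: float = 0.085,
    n_pyramids: int = 7,
    grid_period_mm: float = 3.2,
    center_mm=(0.0, 0.0, 0.0),
) -> PhantomModel:
    """Procedural kidney: ellipsoidal cortex container, solid pelvis wedge,
    grid-based medulla pyramid cluster; mounted in the body cylinder.

    The single radioactive filling solution reaches the cortex and the
    medulla grid gaps, so ``fillable = V_container - V_pelvis -
    (1 - FVF) * V_medulla`` and the medulla-to-cortex mean concentration
    ratio equals the medulla grid FVF.
    """
    if not 50.0 <= fillable_volume_ml <= 300.0:
        raise InvalidParameterError("fillable volume outside plausible range 50-300 mL")
    if not 0 < medulla_fvf < 1:
        raise InvalidParameterError("medulla FVF must lie in (0, 1)")
    denom = 1.0 - pelvis_fraction - (1.0 - medulla_fvf) * medulla_fraction
    v_cont = fillable_volume_ml / denom
    if cortex_concentration is None and total_activity_mbq is None:
        raise InvalidParameterError(
            "provide cortex_concentration or total_activity_mbq"
        )

    ratios = np.array([0.58, 0.42, 1.0])  # x, y, z
    s = (3.0 * v_cont * 1000.0 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    semi = s * ratios
    c0 = np.asarray(center_mm, dtype=float)
    container = _ellipsoid(c0, semi)

    # pelvis: ellipsoid cap beyond the plane y > y0 (one side of the organ)
    u0 = _ellipsoid_cap_u(pelvis_fraction)
    y0 = c0[1] + u0 * semi[1]

    def pelvis_region(pts):
        pts = np.asarray(pts)
        return container(pts) & (pts[:, 1] > y0)

    # medulla: cones with apices near the pelvis face, widening into the cortex
    z_span = 0.55 * semi[2]
    apex_z = c0[2] + np.linspace(-z_span, z_span, n_pyramids)
    apex_y = y0 - 0.02 * semi[1]
    depth = apex_y - (c0[1] - 0.45 * semi[1])

    def medulla_cones(tan_half_angle):
        def pred(pts):
            pts = np.asarray(pts)
            d = apex_y - pts[:, 1]
            ok = (d > 0) & (d <= depth)
            hit = np.zeros(pts.shape[0], dtype=bool)
            rmax = d * tan_half_angle
            for az in apex_z:
                r = np.hypot(pts[:, 0] - c0[0], pts[:, 2] - az)
                hit |= ok & (r <= rmax)
            return hit & container(pts) & (pts[:, 1] <= y0)

        return pred

    bbox = (c0 - semi, c0 + semi)
    target_med = medulla_fraction * v_cont
    probe = centered_grid(
        np.ceil((2 * semi[::-1] + 8.0) / 2.0).astype(int), 2.0, "label"
    )
    lo_t, hi_t = 0.05, 1.5
    for _ in range(24):
        mid = 0.5 * (lo_t + hi_t)
        occ = occupancy(probe, medulla_cones(mid), bbox, 2)
        v = occ.sum() * probe.voxel_volume_ml
        if v < target_med:
            lo_t = mid
        else:
            hi_t = mid
        if abs(v - target_med) < 0.002 * target_med:
            break
    tan_half = 0.5 * (lo_t + hi_t)
    medulla = medulla_cones(tan_half)
    occ = occupancy(probe, medulla, bbox, 2)
    v_med = float(occ.sum() * probe.voxel_volume_ml)
    if v_med > 0.5 * v_cont:
        raise GeometryError("medulla region exceeds plausible container fraction")

    cortex = _subtract(container, pelvis_region, medulla)
    v_pelvis = pelvis_fraction * v_cont

    comp_cortex = Compartment(1, "cortex", 1.0)
    comp_pelvis = Compartment(2, "pelvis", 0.0, RESIN_DENSITY_G_PER_CM3,
                              solid_fraction=1.0)
    comp_med_fill = Compartment(3, "medulla", 0.0)
    comp_med_solid = Compartment(4, "grid_solid", 0.0, RESIN_DENSITY_G_PER_CM3,
                                 solid_fraction=1.0)
    comp_med_avg = Compartment(5, "medulla", 0.0)
    comp_shell = Compartment(6, "wall", 0.0, RESIN_DENSITY_G_PER_CM3,
                             solid_fraction=1.0)

    painters = [
        Painter(comp_cortex.id, cortex, bbox, fill_weight=1.0),
        Painter(comp_pelvis.id, pelvis_region, bbox),
    ]
    med_painters, spec = _grid_painters(
        medulla, bbox, medulla_fvf, 1.0, mode,
        comp_med_fill, comp_med_solid, comp_med_avg, grid_period_mm, c0,
    )
    painters.extend(med_painters)
    shell = _subtract(_ellipsoid(c0, semi + _SHELL_MM), container)
    painters.append(
        Painter(comp_shell.id, shell, (c0 - semi - _SHELL_MM, c0 + semi + _SHELL_MM))
    )
    used = {p.compartment_id for p in painters}
    compartments = [
        cmp
        for cmp in (comp_cortex, comp_pelvis, comp_med_fill, comp_med_solid,
                    comp_med_avg, comp_shell)
        if cmp.id in used
    ]
    # realized fillable volume decides the concentration for a target total
    fillable = measure_fillable_volume(painters)
    if total_activity_mbq is not None:
        cortex_concentration = total_activity_mbq / fillable
    for cmp in compartments:
        cmp.activity_concentration *= cortex_concentration
    total = cortex_concentration * fillable
    cyl = ContainerShape.cylinder(*cylinder_mm)
    return PhantomModel(
        compartments, painters, cyl, mode, fillable, total,
        {
            "container_region": container,
            "container_bbox": bbox,
            "container_volume_ml": v_cont,
            "pelvis_volume_ml": v_pelvis,
            "medulla_volume_ml": v_med,
            "medulla_fvf": medulla_fvf,
            "semi_axes_mm": tuple(semi),
            "grid": spec,
            "cortex_concentration": cortex_concentration,
        },
    )


# ---------------------------------------------------------------------------
# Thyroid phantom
# ---------------------------------------------------------------------------


def build_thyroid_phantom(
    fillable_volume_ml: float = 11.6,
    grid_fvf: float = 0.53,
    hot_spot_diameters_mm: Sequence[float] = (16.0,),
    concentration_mbq_per_ml: float = 3.6,
    neck_mm: tuple[float, float] = (120.0, 160.0),
    mode: str = "compartment_averaged",
    total_activity_mbq: float | None = None,
    hot_spot_lobes: Sequence[int] | None = None,
    grid_period_mm: float = 3.2,
) -> PhantomModel:
    """Procedural thyroid: two ellipsoidal lobes joined by a solid plate,
    fully fillable spherical hot spots inside the grid-filled lobes, mounted
    in a neck-sized cylinder.

    Lobe size is solved so that ``FVF * (V_lobes - V_hot) + V_hot`` matches
    the requested fillable volume.  Hot spots falling partly outside a lobe
    are clipped to it.
    """
    if not 0 < grid_fvf < 1:
        raise InvalidParameterError("grid FVF must lie in (0, 1)")
    diameters = list(hot_spot_diameters_mm)
    if hot_spot_lobes is None:
        hot_spot_lobes = [i % 2 for i in range(len(diameters))]
    v_hot_nominal = sum(4.0 / 3.0 * np.pi * (d / 2) ** 3 / 1000.0 for d in diameters)
    v_lobes = (fillable_volume_ml - (1.0 - grid_fvf) * v_hot_nominal) / grid_fvf
    if v_lobes <= v_hot_nominal:
        raise GeometryError("hot spots do not fit in the solved lobe volume")

    ratios = np.array([10.0, 8.0, 22.0])  # x, y, z semi-axis ratios per lobe
    u = (v_lobes * 1000.0 / (2.0 * 4.0 / 3.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    semi = u * ratios
    lobe_centers = [np.array([-1.4 * semi[0], 0.0, 0.0]),
                    np.array([+1.4 * semi[0], 0.0, 0.0])]
    lobes = [_ellipsoid(c, semi) for c in lobe_centers]
    lobes_region = _union(*lobes)

    # place hot spots inside their lobe, staggered axially
    hot_regions = []
    per_lobe_count = {0: 0, 1: 0}
    for d, li in zip(diameters, hot_spot_lobes):
        k = per_lobe_count[li]
        per_lobe_count[li] += 1
        offset = np.array([0.0, 0.0, (0.35 * semi[2]) * (1 if k % 2 == 0 else -1) * (k > 0)])
        center = lobe_centers[li] + offset
        sph = _sphere(center, d)
        clipped = _intersect(sph, lobes[li])
        # verify the hot spot overlaps its lobe at all
        probe_pts = center[None, :]
        if not lobes[li](probe_pts)[0]:
            raise GeometryError("hot spot center lies outside its lobe")
        hot_regions.append((clipped, center, d))

    lo = np.min([c - semi for c in lobe_centers], axis=0) - _SHELL_MM
    hi = np.max([c + semi for c in lobe_centers], axis=0) + _SHELL_MM
    bbox = (lo, hi)

    # hot-spot volume by voxel counting (handles clipping)
    probe = centered_grid(np.ceil((hi - lo)[::-1] / 1.0 + 2).astype(int), 1.0, "label")
    hot_union = _union(*(h[0] for h in hot_regions)) if hot_regions else None
    if hot_union is not None:
        v_hot = float(
            occupancy(probe, hot_union, bbox, 3).sum() * probe.voxel_volume_ml
        )
    else:
        v_hot = 0.0
    grid_region = (
        _subtract(lobes_region, hot_union) if hot_union is not None else lobes_region
    )
    comp_hot = Compartment(1, "hot_spot", 1.0)
    comp_fill = Compartment(2, "lobe_grid", 0.0)
    comp_solid = Compartment(3, "grid_solid", 0.0, RESIN_DENSITY_G_PER_CM3,
                             solid_fraction=1.0)
    comp_avg = Compartment(4, "lobe_grid", 0.0)
    comp_plate = Compartment(5, "wall", 0.0, RESIN_DENSITY_G_PER_CM3,
                             solid_fraction=1.0)

    painters = []
    if hot_union is not None:
        painters.append(Painter(comp_hot.id, hot_union, bbox, fill_weight=1.0))
    grid_ps, spec = _grid_painters(
        grid_region, bbox, grid_fvf, 1.0, mode,
        comp_fill, comp_solid, comp_avg, grid_period_mm,
    )
    painters.extend(grid_ps)

    plate_size = np.array([2.9 * semi[0], 0.5 * semi[1], 0.5 * semi[2]])
    plate_box = ContainerShape.box(plate_size)
    plate = _subtract(plate_box.contains, lobes_region)
    painters.append(
        Painter(comp_plate.id, plate, (-plate_size / 2, plate_size / 2))
    )
    shell = _subtract(
        _union(*(_ellipsoid(c, semi + _SHELL_MM) for c in lobe_centers)), lobes_region
    )
    painters.append(Painter(comp_plate.id, shell, bbox))

    used = {p.compartment_id for p in painters}
    compartments = [
        cmp
        for cmp in (comp_hot, comp_fill, comp_solid, comp_avg, comp_plate)
        if cmp.id in used
    ]
    fillable = measure_fillable_volume(painters)
    if total_activity_mbq is not None:
        concentration_mbq_per_ml = total_activity_mbq / fillable
    for cmp in compartments:
        cmp.activity_concentration *= concentration_mbq_per_ml
    total = concentration_mbq_per_ml * fillable
    cyl = ContainerShape.cylinder(*neck_mm)
    return PhantomModel(
        compartments, painters, cyl, mode, fillable, total,
        {
            "lobes_region": lobes_region,
            "lobes_bbox": bbox,
            "lobe_centers_mm": [tuple(c) for c in lobe_centers],
            "semi_axes_mm": tuple(semi),
            "lobes_volume_ml": v_lobes,
            "hot_spot_volume_ml": v_hot,
            "hot_spots": [(tuple(c), d) for _, c, d in hot_regions],
            "true_volume_ml": v_lobes,
            "grid": spec,
            "concentration_mbq_per_ml": concentration_mbq_per_ml,
        },
    )


def phantom_config(phantom: PhantomModel) -> dict:
    """Serializable description of a phantom: compartments, concentrations,
    grid parameters, placement and derived volumes (geometry predicates are
    procedural and referenced by the builder metadata, not serialized)."""
    spec = phantom.meta.get("grid")
    return {
        "mode": phantom.mode,
        "cylinder_mm": {
            "diameter": phantom.cylinder.params["diameter_mm"],
            "height": phantom.cylinder.params["height_mm"],
        },
        "fillable_volume_ml": round(phantom.fillable_volume_ml, 4),
        "total_activity_mbq": round(phantom.total_activity_mbq, 4),
        "grid": None
        if spec is None
        else {
            "wall_thickness_mm": spec.wall_thickness_mm,
            "gap_mm": spec.gap_mm,
            "wall_axes": list(spec.wall_axes),
            "phase_mm": list(spec.phase_mm),
        },
        "compartments": [
            {
                "id": c.id,
                "name": c.name,
                "activity_concentration_mbq_per_ml": c.activity_concentration,
                "density_g_per_cm3": c.density,
                "solid_fraction": c.solid_fraction,
            }
            for c in phantom.compartments
        ],
    }


def save_phantom_config(phantom: PhantomModel, path: str) -> None:
    """Write the phantom description as YAML."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(phantom_config(phantom), fh, sort_keys=False)


def region_mask(
    phantom_or_region,
    template: VoxelVolume,
    bbox_mm=None,
    supersample: int = 3,
    threshold: float = 0.5,
) -> np.ndarray:
    """Boolean mask of a phantom region on an image lattice (occupancy >= 0.5).

    Accepts a region predicate or a phantom (whose outer container region is
    taken from ``meta``); used for true-geometry VOIs.
    """
    if isinstance(phantom_or_region, PhantomModel):
        meta = phantom_or_region.meta
        region = meta.get("container_region") or meta.get("lobes_region")
        bbox_mm = meta.get("container_bbox") or meta.get("lobes_bbox")
        if region is None:
            raise InvalidParameterError("phantom has no stored container region")
    else:
        region = phantom_or_region
    occ = occupancy(template, region, bbox_mm, supersample)
    return occ >= threshold
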