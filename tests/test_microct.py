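import numpy as np
import pytest

from gridspect.errors import FitError, InvalidParameterError, SamplingError
from gridspect.gridgen import (
    SOLID,
    ContainerShape,
    GridSpec,
    analytic_fvf,
    rasterize_grid,
)
from gridspect.microct import (
    DefectModel,
    central_peripheral_ratio,
    clean_mask,
    exclude_shell,
    grid_volume_from_ct,
    moment_preserving_threshold,
    printed_grid_sphere_labels,
    synth_microct,
)

VOXEL = 0.2  # mm; 10 voxels across a 2 mm wall

SPEC = GridSpec(2.0, 2.0, ("x", "y"))


@pytest.fixture(scope="module")
def box_labels():
    return rasterize_grid(SPEC, ContainerShape.box(24.0), VOXEL)


@pytest.fixture(scope="module")
def sphere_labels():
    return printed_grid_sphere_labels(SPEC, 30.0, 2.0, VOXEL)


class TestSynthMicroct:
    def test_no_defects_exact_two_level(self, box_labels):
        img = synth_microct(box_labels, DefectModel(), SPEC, seed=0)
        solid = box_labels.values == SOLID
        assert np.all(img.values[solid] == 1000.0)
        assert np.all(img.values[~solid] == 0.0)

    def test_seed_determinism(self, box_labels):
        d = DefectModel(noise_sd=30.0, blur_fwhm_mm=0.3)
        a = synth_microct(box_labels, d, SPEC, seed=5)
        b = synth_microct(box_labels, d, SPEC, seed=5)
        assert np.array_equal(a.values, b.values)
        c = synth_microct(box_labels, d, SPEC, seed=6)
        assert not np.array_equal(a.values, c.values)

    def test_uniform_scale_matches_analytic_thickening(self, box_labels):
        scale = 0.1
        img = synth_microct(box_labels, DefectModel(uniform_scale=scale), SPEC)
        n0 = np.count_nonzero(box_labels.values == SOLID)
        n1 = np.count_nonzero(img.values > 500.0)
        # thickened wall: t -> t*(1+scale) so solid frac 1-(g')^2/p^2, g' = g - s*t
        p = SPEC.period_mm
        g1 = SPEC.gap_mm - scale * SPEC.wall_thickness_mm
        frac0 = 1.0 - analytic_fvf(SPEC)
        frac1 = 1.0 - (g1 / p) ** 2
        assert n1 / n0 == pytest.approx(frac1 / frac0, rel=0.02)

    def test_under_resolved_rejected(self):
        labels = rasterize_grid(SPEC, ContainerShape.box(24.0), 0.9)
        with pytest.raises(SamplingError):
            synth_microct(labels, DefectModel(), SPEC)

    def test_edge_excess_adds_material_at_crossings(self, box_labels):
        img = synth_microct(box_labels, DefectModel(edge_excess_mm=0.3), SPEC)
        n0 = np.count_nonzero(box_labels.values == SOLID)
        n1 = np.count_nonzero(img.values > 500.0)
        assert n1 > n0


class TestMomentThreshold:
    def test_exact_two_level(self):
        vals = np.concatenate([np.full(3000, 10.0), np.full(7000, 50.0)])
        rng = np.random.default_rng(0)
        rng.shuffle(vals)
        img = vals.reshape(10, 10, 100)
        t = moment_preserving_threshold(img)
        assert 10.0 < t < 50.0
        assert (img > t).mean() == pytest.approx(0.700, abs=0.001)

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_two_level(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([np.full(3000, 10.0), np.full(7000, 50.0)])
        vals = vals + rng.normal(0, 2.0, vals.size)
        t = moment_preserving_threshold(vals.reshape(10, 10, 100))
        assert (vals > t).mean() == pytest.approx(0.70, abs=0.01)

    def test_translation_covariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 4000) + (rng.random(4000) > 0.6) * 8.0
        img = vals.reshape(10, 20, 20)
        t0 = moment_preserving_threshold(img)
        t1 = moment_preserving_threshold(img + 13.5)
        assert t1 - t0 == pytest.approx(13.5, abs=1e-6)

    def test_degenerate(self):
        with pytest.raises(InvalidParameterError):
            moment_preserving_threshold(np.full((5, 5, 5), 3.0))


class TestCleanMask:
    def test_isolated_voxel_removed(self):
        m = np.zeros((11, 11, 11), bool)
        m[5, 5, 5] = True
        assert not clean_mask(m).any()

    def test_hole_in_slab_filled(self):
        m = np.zeros((9, 15, 15), bool)
        m[3:6] = True
        m[4, 7, 7] = False
        out = clean_mask(m)
        assert out[4, 7, 7]

    def test_clean_grid_unchanged(self, box_labels):
        solid = box_labels.values == SOLID
        out = clean_mask(solid)
        # compare away from the container border (cleaning erodes open edges)
        sl = (slice(8, -8),) * 3
        assert np.array_equal(out[sl], solid[sl])

    def test_idempotent(self, box_labels):
        solid = box_labels.values == SOLID
        once = clean_mask(solid)
        twice = clean_mask(once)
        assert np.array_equal(once, twice)


class TestExcludeShell:
    def test_perfect_shell_radius(self):
        labels = printed_grid_sphere_labels(None, 40.0, 2.0, VOXEL)
        mask = labels.copy(values=labels.values == SOLID, value_kind="label")
        interior, fit = exclude_shell(mask, shell_thickness_mm=2.0, return_fit=True)
        assert fit.radius_mm == pytest.approx(22.0, abs=0.15)  # outer radius
        assert not interior.values.any()  # shell only: nothing inside

    def test_interior_matches_ground_truth(self, sphere_labels):
        mask = sphere_labels.copy(
            values=sphere_labels.values == SOLID, value_kind="label"
        )
        interior, fit = exclude_shell(mask, shell_thickness_mm=2.0, return_fit=True)
        # ground truth: grid-only voxels inside the same excluded radius
        zz, yy, xx = sphere_labels.coordinate_grids()
        r_cut = fit.radius_mm - 2.0 - 2 * VOXEL
        truth = (
            (sphere_labels.values == SOLID)
            & (zz**2 + yy**2 + xx**2 <= (15.0 - 1e-9) ** 2)
            & (zz**2 + yy**2 + xx**2 <= r_cut**2)
        )
        n_pipe = interior.values.sum()
        n_true = truth.sum()
        assert n_pipe == pytest.approx(n_true, rel=0.01)

    def test_no_shell_raises(self, box_labels):
        mask = box_labels.copy(values=box_labels.values == SOLID, value_kind="label")
        with pytest.raises(FitError):
            exclude_shell(mask)


class TestGridVolume:
    def test_defect_free_self_consistency(self, box_labels):
        solid = box_labels.values == SOLID
        v = grid_volume_from_ct(solid, VOXEL)
        assert v == pytest.approx(solid.sum() * VOXEL**3 / 1000.0)

    def test_empty_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            v = grid_volume_from_ct(np.zeros((4, 4, 4), bool), VOXEL)
        assert v == 0.0


class TestCentralPeripheralRatio:
    def test_ideal_grid_unity(self, sphere_labels):
        solid = sphere_labels.values == SOLID
        sl = solid.shape[0] // 2
        ratio = central_peripheral_ratio(
            solid[sl], VOXEL, 13.0, SPEC.period_mm
        )
        assert ratio == pytest.approx(1.0, abs=0.02)
        ratio_small = central_peripheral_ratio(
            solid[sl], VOXEL, 13.0, SPEC.period_mm, roi_side_periods=1.5
        )
        assert ratio_small == pytest.approx(1.0, abs=0.02)

    def test_central_thickening_lowers_ratio(self, sphere_labels):
        # reduce central void pixels only; ratio must move below unity
        solid = sphere_labels.values == SOLID
        sl = solid.shape[0] // 2
        plane = solid[sl].copy()
        ny, nx = plane.shape
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        central = (yy - (ny - 1) / 2) ** 2 + (xx - (nx - 1) / 2) ** 2 < (
            4.0 / VOXEL
        ) ** 2
        rng = np.random.default_rng(0)
        fill = central & ~plane & (rng.random(plane.shape) < 0.3)
        plane[fill] = True
        ratio = central_peripheral_ratio(
            plane, VOXEL, 13.0, SPEC.period_mm, roi_side_periods=1.5
        )
        assert ratio < 0.98

    def test_roi_outside_rejected(self, sphere_labels):
        solid = sphere_labels.values == SOLID
        sl = solid.shape[0] // 2
        with pytest.raises(InvalidParameterError):
            central_peripheral_ratio(
                solid[sl], VOXEL, 500.0, SPEC.period_mm
            )
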