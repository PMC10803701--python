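import numpy as np
import pytest

from gridspect.errors import (
    EmptyGeometryError,
    InvalidParameterError,
    SamplingError,
)
from gridspect.gridgen import (
    FILLABLE,
    OUTSIDE,
    SOLID,
    ContainerShape,
    GridSpec,
    MassFvfResult,
    analytic_fvf,
    delta_v,
    export_stl,
    fvf_from_labels,
    fvf_from_mass,
    mesh_is_closed,
    mesh_surface_area,
    rasterize_grid,
    read_binary_stl,
    solve_gap_for_fvf,
    solve_wall_for_fvf,
)


class TestAnalyticFvf:
    def test_two_wall_families(self):
        assert analytic_fvf(GridSpec(2, 2, ("x", "y"))) == pytest.approx(0.25)

    def test_one_wall_family(self):
        assert analytic_fvf(GridSpec(2, 2, ("x",))) == pytest.approx(0.5)

    def test_vanishing_wall_limit(self):
        assert analytic_fvf(GridSpec(1e-9, 2.0, ("x", "y"))) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_no_grid_is_unity(self):
        assert analytic_fvf(None) == 1.0

    def test_independent_of_phase(self):
        a = analytic_fvf(GridSpec(2, 3, ("x", "y"), (0.7, 0.1, 0.0)))
        assert a == pytest.approx(analytic_fvf(GridSpec(2, 3, ("x", "y"))))

    @pytest.mark.parametrize("t,g", [(0, 2), (-1, 2), (2, 0), (2, -3)])
    def test_invalid_parameters(self, t, g):
        with pytest.raises(InvalidParameterError):
            GridSpec(t, g)

    def test_invalid_axes(self):
        with pytest.raises(InvalidParameterError):
            GridSpec(2, 2, ())
        with pytest.raises(InvalidParameterError):
            GridSpec(2, 2, ("x", "q"))


class TestSolveGapForFvf:
    def test_quarter(self):
        assert solve_gap_for_fvf(0.25, 2, ("x", "y")).gap_mm == pytest.approx(2.0)

    def test_half_one_family(self):
        assert solve_gap_for_fvf(0.5, 3, ("x",)).gap_mm == pytest.approx(3.0)

    def test_048_closed_form(self):
        g = solve_gap_for_fvf(0.48, 2, ("x", "y")).gap_mm
        f = np.sqrt(0.48)
        assert g == pytest.approx(2 * f / (1 - f), abs=1e-9)
        assert g == pytest.approx(4.511, abs=1e-3)

    def test_048_voxel_counting_oracle(self):
        # independent check: rasterize at 0.1 mm and count
        spec = solve_gap_for_fvf(0.48, 2, ("x", "y"))
        labels = rasterize_grid(spec, ContainerShape.box(4 * spec.period_mm), 0.1)
        assert fvf_from_labels(labels) == pytest.approx(0.48, abs=0.01)

    @pytest.mark.parametrize("target", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_target(self, target):
        with pytest.raises(InvalidParameterError):
            solve_gap_for_fvf(target, 2)

    @pytest.mark.parametrize("fvf", [0.1, 0.28, 0.5, 0.74, 0.99])
    @pytest.mark.parametrize("axes", [("x",), ("x", "y"), ("x", "y", "z")])
    def test_mutual_inverse(self, fvf, axes):
        spec = solve_gap_for_fvf(fvf, 2.0, axes)
        assert analytic_fvf(spec) == pytest.approx(fvf, abs=1e-9)

    @pytest.mark.parametrize("fvf", [0.28, 0.53, 0.74])
    def test_solve_wall_mutual_inverse(self, fvf):
        spec = solve_wall_for_fvf(fvf, 4.0)
        assert spec.period_mm == pytest.approx(4.0)
        assert analytic_fvf(spec) == pytest.approx(fvf, abs=1e-9)


class TestRasterizeGrid:
    def test_empty_spec_sphere(self):
        labels = rasterize_grid(None, ContainerShape.sphere(40), 0.5)
        assert np.count_nonzero(labels.values == SOLID) == 0
        vol = np.count_nonzero(labels.values == FILLABLE) * labels.voxel_volume_ml
        assert vol == pytest.approx(33.51, rel=0.01)

    def test_grid_cube_fraction(self):
        labels = rasterize_grid(GridSpec(2, 2, ("x", "y")), ContainerShape.box(40), 0.5)
        assert fvf_from_labels(labels) == pytest.approx(0.25, abs=0.01)

    def test_phase_translation_invariance(self):
        spec = GridSpec(2, 2, ("x", "y"))
        shifted = GridSpec(2, 2, ("x", "y"), (spec.period_mm / 2,) * 3)
        box = ContainerShape.box(40)
        f1 = fvf_from_labels(rasterize_grid(spec, box, 0.5))
        f2 = fvf_from_labels(rasterize_grid(shifted, box, 0.5))
        assert f1 == pytest.approx(f2, abs=1e-3)

    def test_axis_permutation_invariance(self):
        box = ContainerShape.box(40)
        f1 = fvf_from_labels(rasterize_grid(GridSpec(2, 3, ("x", "y")), box, 0.5))
        f2 = fvf_from_labels(rasterize_grid(GridSpec(2, 3, ("y", "z")), box, 0.5))
        assert f1 == pytest.approx(f2, abs=1e-3)

    def test_coarse_voxel_rejected_with_message(self):
        with pytest.raises(SamplingError, match="min\\(t, g\\)"):
            rasterize_grid(GridSpec(2, 2), ContainerShape.box(40), 1.5)

    def test_first_order_convergence(self):
        # phase-averaged voxel-counting error halves (+-50%) when the voxel
        # halves; single-phase errors oscillate with lattice alignment
        sphere = ContainerShape.sphere(25)
        phases = np.random.default_rng(0).uniform(0, 4, size=(5, 3))
        errs = []
        for v in (0.7, 0.35, 0.175):
            e = [
                abs(
                    fvf_from_labels(
                        rasterize_grid(GridSpec(2, 2, ("x", "y"), tuple(p)), sphere, v)
                    )
                    - 0.25
                )
                for p in phases
            ]
            errs.append(np.mean(e))
        for e0, e1 in zip(errs, errs[1:]):
            assert e1 <= 0.78 * e0 + 2e-4
        assert errs[-1] < 0.005


class TestFvfFromLabels:
    def test_all_fillable(self, small_grid):
        v = small_grid.copy(values=np.full(small_grid.shape, FILLABLE, np.uint8),
                            value_kind="label")
        assert fvf_from_labels(v) == 1.0

    def test_all_solid(self, small_grid):
        v = small_grid.copy(values=np.full(small_grid.shape, SOLID, np.uint8),
                            value_kind="label")
        assert fvf_from_labels(v) == 0.0

    def test_empty_raises(self, small_grid):
        v = small_grid.copy(values=np.full(small_grid.shape, OUTSIDE, np.uint8),
                            value_kind="label")
        with pytest.raises(EmptyGeometryError):
            fvf_from_labels(v)


class TestFvfFromMass:
    def test_zero_mass(self):
        assert float(fvf_from_mass(0.0, 1.192, 33.51)) == 1.0

    def test_full_mass(self):
        assert float(fvf_from_mass(1.192 * 33.51, 1.192, 33.51)) == pytest.approx(0.0)

    def test_partial(self):
        m = 0.72 * 1.192 * 33.51
        assert float(fvf_from_mass(m, 1.192, 33.51)) == pytest.approx(0.28)

    def test_inconsistent_mass_flagged_not_clipped(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            res = fvf_from_mass(2 * 1.192 * 33.51, 1.192, 33.51)
        assert isinstance(res, MassFvfResult)
        assert not res.in_range
        assert res.value == pytest.approx(-1.0)

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            fvf_from_mass(-1.0, 1.192, 33.51)
        with pytest.raises(InvalidParameterError):
            fvf_from_mass(1.0, 0.0, 33.51)


class TestDeltaV:
    def test_equal(self):
        assert delta_v(10.0, 10.0) == 0.0

    def test_design_smaller(self):
        assert delta_v(0.85 * 20, 20.0) == pytest.approx(0.15)

    def test_negative_allowed(self):
        assert delta_v(1.1 * 20, 20.0) == pytest.approx(-0.1)

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            delta_v(10.0, 0.0)


class TestExportStl:
    def test_solid_sphere_closed_and_area(self, tmp_path):
        path = tmp_path / "sphere.stl"
        n = export_stl(ContainerShape.sphere(40), str(path), voxel_size_mm=1.0)
        assert n > 0
        tris = read_binary_stl(str(path))
        assert mesh_is_closed(tris)
        assert mesh_surface_area(tris) == pytest.approx(
            4 * np.pi * 20**2, rel=0.05
        )

    def test_empty_raises(self, tmp_path, small_grid):
        labels = small_grid.copy(
            values=np.zeros(small_grid.shape, np.uint8), value_kind="label"
        )
        with pytest.raises(EmptyGeometryError):
            export_stl(labels, str(tmp_path / "x.stl"))

    def test_coarse_grid_in_sphere_closed(self, tmp_path):
        labels = rasterize_grid(GridSpec(4, 4), ContainerShape.sphere(40), 1.0)
        path = tmp_path / "grid.stl"
        export_stl(labels, str(path))
        assert mesh_is_closed(read_binary_stl(str(path)))
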