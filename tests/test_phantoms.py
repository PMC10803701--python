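import numpy as np
import pytest

from gridspect.errors import GeometryError, InvalidParameterError, SamplingError
from gridspect.phantoms import (
    MU_WATER_CM,
    RESIN_DENSITY_G_PER_CM3,
    assemble_maps,
    build_kidney_phantom,
    build_sphere_phantom,
    build_sphere_set_phantom,
    build_thyroid_phantom,
    occupancy,
    region_mask,
)
from gridspect.volume import centered_grid


class TestSpherePhantom:
    def test_reference_sphere_total_activity(self):
        ph = build_sphere_set_phantom([1.0], concentration_mbq_per_ml=3.02)
        assert ph.total_activity_mbq == pytest.approx(3.02 * 33.51, rel=0.01)

    def test_grid_sphere_total_activity(self):
        ph = build_sphere_set_phantom([0.28], concentration_mbq_per_ml=1.0)
        assert ph.total_activity_mbq == pytest.approx(0.28 * 33.51, rel=0.02)

    def test_fvf_list_monotone_totals(self):
        phs = build_sphere_phantom([0.28, 0.44, 0.60, 0.65], concentration_mbq_per_ml=1.0)
        totals = [p.total_activity_mbq for p in phs]
        assert all(a < b for a, b in zip(totals, totals[1:]))

    def test_placement_error(self):
        with pytest.raises(GeometryError):
            build_sphere_set_phantom([0.5], positions=[(110.0, 0.0, 0.0)])

    def test_map_total_matches_phantom(self):
        ph = build_sphere_set_phantom([0.44, 1.0], concentration_mbq_per_ml=2.0)
        act, _ = assemble_maps(ph)
        assert act.meta["total_activity_mbq"] == pytest.approx(
            ph.total_activity_mbq, rel=0.005
        )

    def test_downsampled_grid_mean_is_fvf_times_conc(self):
        # mean concentration inside the grid region at SPECT voxels
        ph = build_sphere_set_phantom([0.60], concentration_mbq_per_ml=2.0)
        act, _ = assemble_maps(ph)
        zz, yy, xx = act.coordinate_grids()
        interior = zz**2 + yy**2 + xx**2 <= 14.0**2  # well inside the sphere
        realized = ph.meta["spheres"][0]["fvf_realized"]
        assert act.values[interior].mean() == pytest.approx(
            realized * 2.0, rel=0.02
        )

    def test_modes_agree_on_totals(self):
        a = build_sphere_set_phantom([0.44], concentration_mbq_per_ml=1.0,
                                     mode="grid_resolved")
        b = build_sphere_set_phantom([0.44], concentration_mbq_per_ml=1.0,
                                     mode="compartment_averaged")
        assert a.total_activity_mbq == pytest.approx(b.total_activity_mbq, rel=0.005)


class TestKidneyPhantom:
    @pytest.fixture(scope="class")
    def kidney(self):
        return build_kidney_phantom(116.0, 0.36, total_activity_mbq=31.4)

    def test_total_activity(self, kidney):
        assert kidney.total_activity_mbq == pytest.approx(31.4, rel=0.01)

    def test_fillable_volume(self, kidney):
        assert kidney.fillable_volume_ml == pytest.approx(116.0, rel=0.01)

    def test_container_volume_plausible(self, kidney):
        assert 120.0 < kidney.meta["container_volume_ml"] < 140.0

    def test_map_total(self, kidney):
        act, mu = assemble_maps(kidney, mu_water_cm=MU_WATER_CM["lu177"])
        assert act.meta["total_activity_mbq"] == pytest.approx(31.4, rel=0.005)

    def test_mode_totals_agree(self):
        res = build_kidney_phantom(116.0, 0.36, cortex_concentration=0.27,
                                   mode="grid_resolved")
        avg = build_kidney_phantom(116.0, 0.36, cortex_concentration=0.27,
                                   mode="compartment_averaged")
        assert res.total_activity_mbq == pytest.approx(
            avg.total_activity_mbq, rel=0.01
        )

    def test_medulla_fvf_one_matches_cortex(self):
        ph = build_kidney_phantom(116.0, 0.999999, cortex_concentration=0.3,
                                  mode="compartment_averaged")
        concs = {c.name: c.activity_concentration for c in ph.compartments}
        assert concs["medulla"] == pytest.approx(concs["cortex"], rel=1e-3)

    def test_averaged_medulla_ratio(self, kidney):
        concs = {c.name: c.activity_concentration for c in kidney.compartments}
        assert concs["medulla"] / concs["cortex"] == pytest.approx(0.36)

    def test_pelvis_is_cold(self, kidney):
        pelvis = [c for c in kidney.compartments if c.name == "pelvis"][0]
        assert pelvis.activity_concentration == 0.0
        assert pelvis.solid_fraction == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            build_kidney_phantom(10.0, 0.36, cortex_concentration=1.0)
        with pytest.raises(InvalidParameterError):
            build_kidney_phantom(116.0, 1.5, cortex_concentration=1.0)
        with pytest.raises(InvalidParameterError):
            build_kidney_phantom(116.0, 0.36)


class TestThyroidPhantom:
    def test_total_is_concentration_times_fillable(self):
        ph = build_thyroid_phantom(11.6, 0.53, (16.0,), 3.6)
        assert ph.fillable_volume_ml == pytest.approx(11.6, rel=0.01)
        assert ph.total_activity_mbq == pytest.approx(3.6 * 11.6, rel=0.01)

    def test_averaged_lobe_to_hotspot_ratio(self):
        ph = build_thyroid_phantom(11.6, 0.53, (16.0,), 3.6,
                                   mode="compartment_averaged")
        concs = {c.name: c.activity_concentration for c in ph.compartments}
        assert concs["lobe_grid"] / concs["hot_spot"] == pytest.approx(0.53)

    def test_zero_hot_spots_uniform(self):
        ph = build_thyroid_phantom(11.6, 0.53, (), 3.6)
        names = {c.name for c in ph.compartments}
        assert "hot_spot" not in names

    def test_outer_volume_near_reported(self):
        # fillable 11.6 mL at FVF 53% with one 16 mm hot spot implies a
        # ~20 mL lobe volume (plus plate/walls -> the reported ~22 mL)
        ph = build_thyroid_phantom(11.6, 0.53, (16.0,), 3.6)
        assert ph.meta["lobes_volume_ml"] == pytest.approx(20.0, abs=0.7)

    def test_total_activity_override(self):
        ph = build_thyroid_phantom(11.6, 0.53, (16.0,), total_activity_mbq=40.0)
        assert ph.total_activity_mbq == pytest.approx(40.0, rel=1e-6)

    def test_hot_spot_outside_lobe_raises(self):
        with pytest.raises(GeometryError):
            build_thyroid_phantom(11.6, 0.53, (400.0,), 3.6)


class TestAssembleMaps:
    def test_water_mu_uniform(self):
        ph = build_sphere_set_phantom([1.0], concentration_mbq_per_ml=1.0)
        _, mu = assemble_maps(ph, mu_water_cm=0.154)
        inside = mu.values > 0.9 * 0.154
        assert np.unique(np.round(mu.values[inside], 10)).size == 1
        # outside the cylinder: zero
        zz, yy, xx = mu.coordinate_grids()
        far = yy**2 + xx**2 > 115.0**2
        assert np.all(mu.values[far] == 0)

    def test_resin_aware_differs_only_in_solid(self):
        ph = build_sphere_set_phantom([0.44], concentration_mbq_per_ml=1.0)
        _, mu_w = assemble_maps(ph, mu_water_cm=0.154, medium="water")
        _, mu_r = assemble_maps(ph, mu_water_cm=0.154, medium="resin_aware")
        diff = mu_r.values - mu_w.values
        assert diff.min() >= -1e-12
        # fully solid voxels scale by the density ratio
        assert diff.max() <= 0.154 * (RESIN_DENSITY_G_PER_CM3 - 1.0) + 1e-9
        zz, yy, xx = mu_w.coordinate_grids()
        outside_sphere = zz**2 + yy**2 + xx**2 > 25.0**2
        assert np.all(np.abs(diff[outside_sphere]) < 1e-12)

    def test_coarse_supersample_rejected(self):
        ph = build_sphere_set_phantom([0.28], concentration_mbq_per_ml=1.0)
        with pytest.raises(SamplingError):
            assemble_maps(ph, supersample=2)

    def test_region_mask_volume(self):
        ph = build_kidney_phantom(116.0, 0.36, total_activity_mbq=31.4)
        tmpl = centered_grid((40, 40, 40), 4.42)
        mask = region_mask(ph, tmpl)
        vol = mask.sum() * tmpl.voxel_volume_ml
        assert vol == pytest.approx(ph.meta["container_volume_ml"], rel=0.05)


class TestOccupancy:
    def test_full_region_is_one(self):
        g = centered_grid((8, 8, 8), 2.0)
        occ = occupancy(g, lambda p: np.ones(len(p), bool), None, 3)
        assert np.allclose(occ, 1.0)

    def test_half_space(self):
        g = centered_grid((8, 8, 8), 2.0)
        occ = occupancy(g, lambda p: p[:, 0] > 0, None, 6)
        assert occ.sum() == pytest.approx(occ.size / 2.0, rel=0.02)

    def test_deterministic_for_seed(self):
        g = centered_grid((6, 6, 6), 2.0)
        sph = lambda p: np.sum(p**2, axis=1) < 16.0
        a = occupancy(g, sph, None, 4, seed=3)
        b = occupancy(g, sph, None, 4, seed=3)
        assert np.array_equal(a, b)


class TestPhantomConfig:
    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        from gridspect.phantoms import phantom_config, save_phantom_config

        ph = build_thyroid_phantom(11.6, 0.53, (16.0,), 3.6)
        cfg = phantom_config(ph)
        assert cfg["fillable_volume_ml"] == pytest.approx(11.6, rel=0.01)
        assert cfg["grid"]["wall_axes"] == ["x", "y"]
        path = tmp_path / "phantom.yaml"
        save_phantom_config(ph, str(path))
        loaded = yaml.safe_load(path.read_text())
        assert loaded == cfg
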