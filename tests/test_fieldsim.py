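"""Trial layout, canopy truth and raw sensor stream simulation."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from phenomass import fieldsim as fs


class TestLayout:
    def test_default_trial_has_160_plots_and_480_rows(self, default_layout):
        assert default_layout.n_plots == 160
        assert default_layout.n_rows == 480

    def test_single_plot_invariants(self):
        cfg = fs.SimulationConfig(seed=0, n_plots=1, plots_per_column=1)
        layout = fs.generate_layout(cfg)
        assert layout.n_plots == 1
        assert layout.n_rows == 3
        _, plot_poly = layout.plots[0]
        minx, miny, maxx, maxy = plot_poly.bounds
        for _, _, row_poly in layout.rows:
            rx0, ry0, rx1, ry1 = row_poly.bounds
            assert rx0 >= minx and ry0 >= miny and rx1 <= maxx and ry1 <= maxy
        polys = [p for _, _, p in layout.rows]
        for i in range(3):
            for j in range(i + 1, 3):
                assert polys[i].disjoint(polys[j])

    def test_rows_disjoint_across_default_trial(self, default_layout):
        # adjacent rows within each plot are the tight case
        by_plot = {}
        for rid, pid, poly in default_layout.rows:
            by_plot.setdefault(pid, []).append(poly)
        for polys in by_plot.values():
            assert polys[0].disjoint(polys[1]) and polys[1].disjoint(polys[2])

    def test_layout_deterministic(self):
        cfg = fs.SimulationConfig(seed=3, n_plots=8, plots_per_column=4)
        a = fs.generate_layout(cfg)
        b = fs.generate_layout(cfg)
        for (ra, pa, poly_a), (rb, pb, poly_b) in zip(a.rows, b.rows):
            assert (ra, pa) == (rb, pb)
            assert poly_a.equals_exact(poly_b, 0.0)

    def test_plot_dimensions(self, default_layout):
        _, poly = default_layout.plots[0]
        minx, miny, maxx, maxy = poly.bounds
        assert maxx - minx == pytest.approx(1.8)
        assert maxy - miny == pytest.approx(4.0)

    @pytest.mark.parametrize("bad", [
        {"n_plots": 0}, {"plot_dims": (0.0, 4.0)}, {"row_spacing": -0.1},
        {"noise_sd": -1.0}, {"reproductive_fraction": 1.5}, {"season": "autumn"},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            fs.SimulationConfig(seed=0, **bad)


class TestCanopyTruth:
    def test_generative_formula_noise_free(self):
        cfg = fs.SimulationConfig(seed=5, n_plots=1, plots_per_column=1,
                                  biomass_coefficient=1000.0, noise_sd=0.0,
                                  season="late_spring", reproductive_fraction=0.0)
        layout = fs.generate_layout(cfg)
        truth = fs.simulate_canopies(layout, cfg)
        for rc in truth.rows:
            assert truth.true_FM[rc.row_id] == pytest.approx(1000.0 * rc.volume() * rc.density)

    def test_same_seed_identical_truth(self):
        cfg = fs.SimulationConfig(seed=11, n_plots=2, plots_per_column=2)
        layout = fs.generate_layout(cfg)
        a = fs.simulate_canopies(layout, cfg)
        b = fs.simulate_canopies(layout, cfg)
        assert a.true_FM == b.true_FM
        for ra, rb in zip(a.rows, b.rows):
            np.testing.assert_array_equal(ra.heights, rb.heights)
            np.testing.assert_array_equal(ra.centers, rb.centers)

    def test_fm_tracks_volume_density_product_under_low_noise(self, default_layout):
        # noise at ~1% of mean FM keeps the generative correlation >= 0.99
        cfg0 = fs.SimulationConfig(seed=13, noise_sd=0.0)
        clean = fs.simulate_canopies(default_layout, cfg0)
        mean_fm = np.mean(list(clean.true_FM.values()))
        cfg = fs.SimulationConfig(seed=13, noise_sd=0.01 * mean_fm)
        truth = fs.simulate_canopies(default_layout, cfg)
        tt = truth.truth_table()
        assert len(tt) == 480
        r = np.corrcoef(tt.true_FM, tt.true_volume * tt.true_density)[0, 1]
        assert r >= 0.99

    def test_volume_above_matches_quadrature(self, one_plot_truth):
        layout, truth = one_plot_truth
        rc = truth.rows[0]
        poly = layout.row_polygon(rc.row_id)
        x0, y0, x1, y1 = poly.bounds
        xs = np.arange(x0 + 0.001, x1, 0.002)
        ys = np.arange(y0 + 0.001, y1, 0.002)
        gx, gy = np.meshgrid(xs, ys)
        for datum in (0.0, 0.05, 0.10):
            quad = float(np.clip(rc.surface(gx, gy) - datum, 0, None).sum() * 0.002**2)
            assert rc.volume_above(datum) == pytest.approx(quad, rel=5e-3)

    def test_surface_zero_outside_row_footprint(self, one_plot_truth):
        layout, truth = one_plot_truth
        rc = truth.rows[0]
        poly = layout.row_polygon(rc.row_id)
        x0, y0, x1, y1 = poly.bounds
        far = rc.surface(np.array([x1 + 0.5, x0 - 0.5]), np.array([y0, y1]))
        np.testing.assert_array_equal(far, 0.0)

    def test_summer_reproductive_spikes_increase_max_height(self):
        base = dict(seed=21, n_plots=1, plots_per_column=1, season="summer")
        layout = fs.generate_layout(fs.SimulationConfig(**base))
        none = fs.simulate_canopies(layout, fs.SimulationConfig(**base, reproductive_fraction=0.0))
        some = fs.simulate_canopies(layout, fs.SimulationConfig(**base, reproductive_fraction=0.9))
        assert max(rc.heights.max() for rc in some.rows) > max(rc.heights.max() for rc in none.rows)


class TestLidarSurvey:
    def test_frame_and_fix_counts_for_one_second_drive(self):
        # plot length = drive_speed * 1 s -> each pass lasts exactly 1 s
        sc = fs.ScannerConfig(range_noise_sd=0.0)
        cfg = fs.SimulationConfig(seed=2, n_plots=1, plots_per_column=1,
                                  plot_dims=(1.8, sc.drive_speed * 1.0), plants_per_row=4)
        layout = fs.generate_layout(cfg)
        truth = fs.simulate_canopies(layout, cfg)
        frames, track = fs.simulate_lidar_survey(truth, sc, seed=0, row_ids=[1])
        assert len(frames) == math.ceil(1.0 * sc.scan_rate) == 500
        assert len(track) == math.ceil(1.0 * sc.gps_rate) == 5

    def test_bare_ground_nadir_range_is_sensor_height(self):
        cfg = fs.SimulationConfig(seed=2, n_plots=1, plots_per_column=1,
                                  canopy_height_range=(0.0, 0.0), reproductive_fraction=0.0)
        layout = fs.generate_layout(cfg)
        truth = fs.simulate_canopies(layout, cfg)
        sc = fs.ScannerConfig(scan_rate=20.0, range_noise_sd=0.0)
        frames, _ = fs.simulate_lidar_survey(truth, sc, seed=0, row_ids=[1])
        nadir = int(np.flatnonzero(sc.beam_angles == 90.0)[0])
        ranges = np.array([f.ranges[nadir] for f in frames])
        np.testing.assert_allclose(ranges, sc.sensor_height, atol=0.003)

    def test_slab_under_sensor_shortens_nadir_range(self):
        # a 0.5 m slab directly under the sensor: first return at 1.127 - 0.5
        angles = np.deg2rad(fs.ScannerConfig().beam_angles)
        profile_x = np.arange(-1.5, 1.5, 0.002)
        profile_h = np.full_like(profile_x, 0.5)
        ranges = fs._first_return(profile_x, profile_h, angles, 0.0, 1.127)
        nadir = int(np.flatnonzero(fs.ScannerConfig().beam_angles == 90.0)[0])
        assert ranges[nadir] == pytest.approx(0.627, abs=0.003)

    def test_survey_reproducible_for_fixed_seed(self, one_plot_truth):
        _, truth = one_plot_truth
        sc = fs.ScannerConfig(scan_rate=20.0)
        f1, t1 = fs.simulate_lidar_survey(truth, sc, seed=9, row_ids=[1])
        f2, t2 = fs.simulate_lidar_survey(truth, sc, seed=9, row_ids=[1])
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.ranges, b.ranges)
        assert [(f.easting, f.northing) for f in t1] == [(f.easting, f.northing) for f in t2]


class TestMultispectral:
    def test_tarp_panel_linear_dn_response(self, one_plot_truth):
        layout, truth = one_plot_truth
        cam = fs.MultispectralConfig(gain=1000.0, offset=50.0, dn_noise_sd=0.0)
        tarp = fs.default_tarp(layout)
        rasters = fs.simulate_multispectral(truth, layout, tarp, seed=0, camera=cam)
        panel = tarp[-1]  # nominal 0.33
        for band in rasters.values():
            xs, ys = band.pixel_centers()
            import shapely

            inside = shapely.contains_xy(panel.polygon, xs.ravel(), ys.ravel())
            assert band.data.ravel()[inside].mean() == pytest.approx(380.0)

    def test_bare_soil_ndvi_near_zero_after_calibration(self):
        from phenomass import spectral_metrics as sm

        cfg = fs.SimulationConfig(seed=2, n_plots=1, plots_per_column=1,
                                  canopy_height_range=(0.0, 0.0), reproductive_fraction=0.0)
        layout = fs.generate_layout(cfg)
        truth = fs.simulate_canopies(layout, cfg)
        tarp = fs.default_tarp(layout)
        rasters = fs.simulate_multispectral(truth, layout, tarp, seed=0)
        nir, _ = sm.calibrate_band(rasters["nir"], tarp)
        red, _ = sm.calibrate_band(rasters["red"], tarp)
        value = sm.zonal_mean(sm.ndvi(nir, red), layout.row_polygon(1))
        assert abs(value) < 0.1

    def test_rasters_deterministic_for_seed(self, one_plot_truth):
        layout, truth = one_plot_truth
        cam = fs.MultispectralConfig(dn_noise_sd=2.0)
        a = fs.simulate_multispectral(truth, layout, seed=4, camera=cam)
        b = fs.simulate_multispectral(truth, layout, seed=4, camera=cam)
        for band in a:
            np.testing.assert_array_equal(a[band].data, b[band].data)


class TestSonar:
    class _FlatTruth:
        def __init__(self, height):
            self._h = height

        def surface(self, x, y):
            return np.broadcast_to(np.asarray(self._h, dtype=float),
                                   np.broadcast(np.asarray(x), np.asarray(y)).shape)

    def _layout(self):
        cfg = fs.SimulationConfig(seed=0, n_plots=1, plots_per_column=1)
        return fs.generate_layout(cfg)

    def test_flat_canopy_distance(self):
        layout = self._layout()
        sonar = fs.SonarConfig(noise_sd=0.0)
        samples = fs.simulate_sonar(self._FlatTruth(0.25), layout, seed=0, sonar=sonar)
        assert all(s.distance == pytest.approx(0.35) for s in samples)

    def test_bare_ground_distance_is_mount_height(self):
        layout = self._layout()
        sonar = fs.SonarConfig(noise_sd=0.0)
        samples = fs.simulate_sonar(self._FlatTruth(0.0), layout, seed=0, sonar=sonar)
        assert all(s.distance == pytest.approx(sonar.mount_height) for s in samples)

    def test_sample_spacing_is_speed_over_rate(self):
        layout = self._layout()
        sonar = fs.SonarConfig(noise_sd=0.0)
        samples = [s for s in fs.simulate_sonar(self._FlatTruth(0.1), layout, seed=0,
                                                sonar=sonar, row_ids=[1])
                   if s.sensor == 1]
        spacing = np.diff(sorted(s.y for s in samples))
        np.testing.assert_allclose(spacing, sonar.drive_speed / sonar.sample_rate)
        assert spacing[0] == pytest.approx(0.14)


class TestPhenotypeTable:
    def test_fm_follows_generative_law_noise_free(self):
        df = fs.simulate_phenotype_table(n_rows=30, seed=1, rho=1000.0, noise_sd=0.0)
        np.testing.assert_allclose(df.FM, 1000.0 * df.LV * df.LV_Den)

    def test_target_r2_calibration_hits_requested_level(self):
        from phenomass import models

        df = fs.simulate_phenotype_table(n_rows=480, seed=3, target_r2=0.9)
        fit = models.fit_ols(models.expand_model("M4"), df)
        assert models.model_metrics(fit).r_squared == pytest.approx(0.9, abs=0.03)

    def test_deterministic(self):
        a = fs.simulate_phenotype_table(n_rows=30, seed=8, target_r2=0.8)
        b = fs.simulate_phenotype_table(n_rows=30, seed=8, target_r2=0.8)
        assert a.equals(b)

    def test_row_count_must_be_multiple_of_three(self):
        with pytest.raises(ValueError):
            fs.simulate_phenotype_table(n_rows=20, seed=0)
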