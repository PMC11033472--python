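"""Module-conditioned densities, radial profiles, KS comparison, anisotropy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modmap import (
    InjectionSite,
    PlanarImage,
    RoiSpec,
    anisotropy_aspect_ratio,
    detect_injection_center,
    generate_module_field,
    ks_compare,
    point_module_density,
    radial_density_profile,
    roi_quantile_density,
)
from modmap.image import ModuleMap, ParameterError
from modmap.quantify import EmptySampleError, assign_point_modules, roi_class_means


def uniform_module_map(shape, label=1, pixel_size_um=5.0):
    return ModuleMap(np.full(shape, label, dtype=np.int16), pixel_size_um=pixel_size_um)


def checkerboard_map(shape, pixel_size_um=5.0):
    """Label 1 (interpatch) / 6 (patch) checkerboard covering the frame."""
    r, c = np.mgrid[0 : shape[0], 0 : shape[1]]
    labels = np.where((r + c) % 2 == 0, 6, 1).astype(np.int16)
    return ModuleMap(labels, pixel_size_um=pixel_size_um)


class TestInjectionCenter:
    def test_single_saturated_pixel(self):
        img = np.ones((40, 40))
        img[10, 30] = 100.0
        site = detect_injection_center(PlanarImage(img, 5.0), 0.999)
        assert site.center_xy_um == (150.0, 50.0)

    def test_gaussian_blob_centroid_within_one_pixel(self):
        y, x = np.mgrid[0:64, 0:64]
        blob = np.exp(-((x - 40.3) ** 2 + (y - 21.7) ** 2) / (2 * 6.0**2))
        site = detect_injection_center(PlanarImage(blob, 5.0), 0.99)
        assert abs(site.center_xy_um[0] - 40.3 * 5.0) < 5.0
        assert abs(site.center_xy_um[1] - 21.7 * 5.0) < 5.0

    def test_scene_center_recovered_within_10um(self, reduced_scene):
        site = detect_injection_center(reduced_scene.axon_field)
        cx, cy = reduced_scene.injection.center_xy_um
        assert abs(site.center_xy_um[0] - cx) < 10.0
        assert abs(site.center_xy_um[1] - cy) < 10.0


class TestRoiQuantileDensity:
    def test_uniform_signal_all_means_one(self, rng):
        _, gt = generate_module_field(1, (320, 320), 5.0, 120.0)
        signal = PlanarImage(np.ones(gt.shape), 5.0)
        roi = RoiSpec(50.0, 50.0, 200.0, 200.0)
        tab = roi_quantile_density(signal, gt, [roi])
        assert np.allclose(tab["mean_intensity"], 1.0)

    def test_signal_equal_to_label_recovers_labels(self, rng):
        _, gt = generate_module_field(2, (320, 320), 5.0, 120.0)
        signal = PlanarImage(gt.quantile_label.astype(float), 5.0)
        tab = roi_quantile_density(signal, gt, [RoiSpec(0.0, 0.0, 315.0, 315.0)])
        assert np.allclose(tab["mean_intensity"], tab["quantile"])

    def test_matches_brute_force_grouping(self, rng):
        _, gt = generate_module_field(3, (320, 320), 5.0, 120.0)
        signal = PlanarImage(rng.uniform(0.0, 2.0, gt.shape), 5.0)
        roi = RoiSpec(25.0, 40.0, 200.0, 150.0)
        tab = roi_quantile_density(signal, gt, [roi]).set_index("quantile")
        rs, cs = roi.pixel_slice(5.0, gt.shape)
        for q in range(1, 7):
            vals = [
                signal.pixels[r, c]
                for r in range(rs.start, rs.stop)
                for c in range(cs.start, cs.stop)
                if gt.quantile_label[r, c] == q
            ]
            assert tab.loc[q, "mean_intensity"] == pytest.approx(
                np.mean(vals), abs=1e-12
            )
            assert tab.loc[q, "pixel_count"] == len(vals)

    def test_conservation_sum_mean_times_count(self, rng):
        _, gt = generate_module_field(4, (320, 320), 5.0, 120.0)
        signal = PlanarImage(rng.uniform(0.0, 2.0, gt.shape), 5.0)
        roi = RoiSpec(0.0, 0.0, 315.0, 315.0)
        tab = roi_quantile_density(signal, gt, [roi])
        total = (tab["mean_intensity"] * tab["pixel_count"]).sum()
        rs, cs = roi.pixel_slice(5.0, gt.shape)
        assert total == pytest.approx(signal.pixels[rs, cs].sum(), rel=1e-12)

    def test_missing_quantile_absent_not_zero(self):
        mm = uniform_module_map((20, 20), label=6)
        signal = PlanarImage(np.ones((20, 20)), 5.0)
        tab = roi_quantile_density(signal, mm, [RoiSpec(0.0, 0.0, 90.0, 90.0)])
        assert set(tab["quantile"]) == {6}


class TestRadialProfile:
    def test_uniform_field_single_class_flat_at_one(self):
        mm = uniform_module_map((100, 100), label=1)
        signal = PlanarImage(np.ones((100, 100)), 5.0)
        site = InjectionSite(center_xy_um=(250.0, 250.0))
        prof = radial_density_profile(
            mm, site, signal=signal, bin_width_um=25.0, exclusion_radius_um=50.0
        )
        assert np.allclose(prof.normalized["interpatch"], 1.0)
        assert np.all(np.isnan(prof.normalized["patch"]))
        assert prof.bin_edges_um[0] == 50.0

    def test_planted_ratio_recovered_per_bin(self):
        from modmap import generate_axon_field

        _, gt = generate_module_field(7, (1280, 1280), 10.0, 120.0)
        site = InjectionSite(center_xy_um=(640.0, 640.0), core_radius_um=0.0)
        fld = generate_axon_field(gt, site, rho=3.0, anisotropy_a=1.0,
                                  decay_length_um=400.0)
        prof = radial_density_profile(
            gt, injection=site, signal=fld, bin_width_um=50.0,
            exclusion_radius_um=100.0,
        )
        ratio = prof.density["interpatch"] / prof.density["patch"]
        ok = np.isfinite(ratio)
        assert ok.sum() >= 8
        assert np.allclose(ratio[ok], 3.0, rtol=0.05)

    def test_points_inside_exclusion_give_zero_bins(self):
        mm = uniform_module_map((100, 100), label=1)
        site = InjectionSite(center_xy_um=(250.0, 250.0))
        pts = pd.DataFrame({"x_um": [250.0, 260.0], "y_um": [250.0, 240.0]})
        prof = radial_density_profile(
            mm, site, points=pts, bin_width_um=25.0, exclusion_radius_um=100.0
        )
        assert np.all(prof.density["interpatch"] == 0.0)

    def test_normalization_joint_peak_is_one(self, reduced_scene):
        prof = radial_density_profile(
            reduced_scene.gt_module_map,
            reduced_scene.injection,
            signal=reduced_scene.axon_field,
            bin_width_um=50.0,
            exclusion_radius_um=150.0,
        )
        joint = np.concatenate(
            [prof.normalized["patch"], prof.normalized["interpatch"]]
        )
        assert np.nanmax(joint) == pytest.approx(1.0)

    def test_annulus_sums_match_pixel_loop(self, rng):
        mm = checkerboard_map((40, 40))
        signal = PlanarImage(rng.uniform(0.0, 1.0, (40, 40)), 5.0)
        site = InjectionSite(center_xy_um=(100.0, 100.0))
        prof = radial_density_profile(
            mm, site, signal=signal, bin_width_um=25.0, exclusion_radius_um=0.0,
            max_radius_um=100.0,
        )
        # explicit pixel loop oracle
        for b in range(len(prof.bin_edges_um) - 1):
            lo, hi = prof.bin_edges_um[b], prof.bin_edges_um[b + 1]
            for cls, want_label in (("patch", 6), ("interpatch", 1)):
                tot, npix = 0.0, 0
                for r in range(40):
                    for c in range(40):
                        d = np.hypot(c * 5.0 - 100.0, r * 5.0 - 100.0)
                        if lo <= d < hi and mm.quantile_label[r, c] == want_label:
                            tot += signal.pixels[r, c]
                            npix += 1
                if npix == 0:
                    assert np.isnan(prof.density[cls][b])
                else:
                    assert prof.density[cls][b] == pytest.approx(
                        tot / (npix * 25.0), abs=1e-12
                    )


class TestPointDensity:
    def test_all_points_in_interpatch_ratio_zero(self):
        mm = checkerboard_map((40, 40))
        rc = np.argwhere(mm.interpatch_mask)[:10]
        pts = pd.DataFrame({"x_um": rc[:, 1] * 5.0, "y_um": rc[:, 0] * 5.0})
        tab = point_module_density(pts, mm, [RoiSpec(0.0, 0.0, 195.0, 195.0)])
        assert tab.loc[0, "patch_density_per_mm2"] == 0.0
        assert tab.loc[0, "patch_interpatch_ratio"] == 0.0

    def test_density_definition_points_per_mm2(self):
        mm = uniform_module_map((200, 200), label=6)  # 1 mm x 1 mm at 5 um/px
        pts = pd.DataFrame(
            {"x_um": np.linspace(100, 900, 10), "y_um": np.linspace(100, 900, 10)}
        )
        tab = point_module_density(pts, mm, [RoiSpec(0.0, 0.0, 1000.0, 1000.0)])
        assert tab.loc[0, "patch_density_per_mm2"] == pytest.approx(10.0)
        assert np.isnan(tab.loc[0, "patch_interpatch_ratio"])  # no interpatch area

    def test_homogeneous_points_ratio_near_one(self, rng):
        mm = checkerboard_map((100, 100))
        n = 20000
        pts = pd.DataFrame(
            {"x_um": rng.uniform(0, 495, n), "y_um": rng.uniform(0, 495, n)}
        )
        tab = point_module_density(pts, mm, [RoiSpec(0.0, 0.0, 490.0, 490.0)])
        assert tab.loc[0, "patch_interpatch_ratio"] == pytest.approx(1.0, rel=0.1)

    def test_module_assignment_labels(self):
        mm = checkerboard_map((10, 10))
        pts = pd.DataFrame({"x_um": [0.0, 5.0, -50.0], "y_um": [0.0, 0.0, 0.0]})
        out = assign_point_modules(pts, mm)
        assert list(out["module"]) == ["patch", "interpatch", "background"]


class TestKsCompare:
    def test_identical_samples(self):
        x = np.arange(10.0)
        res = ks_compare(x, x)
        assert res.ks_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = ks_compare([0.1, 0.2], [0.8, 0.9])
        assert res.ks_statistic == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySampleError):
            ks_compare([], [1.0])

    def test_exact_vs_asymptotic_switch(self):
        small = ks_compare(np.arange(12.0), np.arange(12.0) + 0.5)
        big = ks_compare(np.arange(30.0), np.arange(30.0) + 0.5)
        assert small.method == "exact" and big.method == "asymp"

    def test_null_rejection_rate_matches_exact_test_size(self):
        """At n=m=12 the KS statistic is discrete: the rejection region at
        alpha=0.05 is D >= 7/12, whose exact null probability is 0.0314.
        The simulated rejection rate must match that size (and stay below
        the nominal alpha)."""
        exact_size = float(
            stats.ks_2samp(
                np.arange(12.0), np.arange(12.0) + 6.5, method="exact"
            ).pvalue
        )
        assert exact_size == pytest.approx(0.0314, abs=0.001)
        rng = np.random.default_rng(2024)
        n_rep = 2000
        rej = sum(
            ks_compare(rng.standard_normal(12), rng.standard_normal(12)).p_value
            <= 0.05
            for _ in range(n_rep)
        )
        rate = rej / n_rep
        slack = 1.96 * np.sqrt(exact_size * (1 - exact_size) / n_rep)
        assert abs(rate - exact_size) <= slack
        assert rate <= 0.05


class TestAnisotropy:
    def test_isotropic_disc_ratio_one(self):
        y, x = np.mgrid[0:101, 0:101]
        disc = (np.hypot(x - 50, y - 50) <= 40).astype(float)
        res = anisotropy_aspect_ratio(
            signal=PlanarImage(disc, 5.0), intensity_quantile_threshold=0.8
        )
        assert res.aspect_ratio == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("angle_deg", [0.0, 37.0])
    def test_gaussian_ratio_and_rotation_invariance(self, angle_deg):
        y, x = np.mgrid[0:201, 0:201].astype(float)
        th = np.deg2rad(angle_deg)
        u = (x - 100) * np.cos(th) + (y - 100) * np.sin(th)
        v = -(x - 100) * np.sin(th) + (y - 100) * np.cos(th)
        fld = np.exp(-(u**2 / (2 * 28.0**2) + v**2 / (2 * 20.0**2)))
        res = anisotropy_aspect_ratio(
            signal=PlanarImage(fld, 5.0), intensity_quantile_threshold=0.9
        )
        assert res.aspect_ratio == pytest.approx(1.4, abs=0.05)
        expected_angle = angle_deg % 180.0
        assert res.major_axis_angle_deg == pytest.approx(expected_angle, abs=2.0)

    def test_collinear_support_degenerate(self):
        pts = pd.DataFrame({"x_um": [0.0, 1.0, 2.0], "y_um": [0.0, 0.0, 0.0]})
        with pytest.raises(ParameterError):
            anisotropy_aspect_ratio(points=pts)

    def test_scale_invariance_of_ratio(self, reduced_scene):
        a = anisotropy_aspect_ratio(signal=reduced_scene.axon_field)
        scaled = reduced_scene.axon_field.with_pixels(
            reduced_scene.axon_field.pixels * 17.0
        )
        b = anisotropy_aspect_ratio(signal=scaled)
        assert a.aspect_ratio == pytest.approx(b.aspect_ratio, rel=1e-9)
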