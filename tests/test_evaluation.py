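"""Profiles, FWHM, ROI statistics, distortion reports and trend fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import stereoct as sc
from stereoct.errors import EvaluationError
from stereoct.evaluate import Profile

from conftest import small_phantom_spec


def profile_from(values, step=0.5, start=0.0):
    v = np.asarray(values, dtype=float)
    return Profile(start + step * np.arange(v.size), v)


def rect_profile(width_mm, step=0.5, length_mm=40.0, high=100.0, low=0.0, center=None):
    pos = np.arange(-length_mm / 2, length_mm / 2 + step / 2, step)
    c = 0.0 if center is None else center
    vals = np.where(np.abs(pos - c) <= width_mm / 2, high, low)
    return Profile(pos, vals)


class TestExtractProfile:
    def test_constant_volume_yields_flat_profile(self):
        vol = sc.Volume(np.full((10, 12, 14), 100.0), spacing=(1.0, 1.0, 1.0))
        prof = sc.extract_profile(vol, vol.center_mm, "AP")
        assert np.all(prof.values_hu == 100.0)
        assert prof.positions_mm.size == 12

    def test_sample_count_matches_extent_over_step(self):
        vol = sc.Volume(np.zeros((10, 12, 14)), spacing=(0.5, 1.0, 2.0))
        assert sc.extract_profile(vol, vol.center_mm, "LR").positions_mm.size == 14
        assert sc.extract_profile(vol, vol.center_mm, "SI").positions_mm.size == 10

    def test_line_outside_volume_rejected(self):
        vol = sc.Volume(np.zeros((10, 12, 14)))
        with pytest.raises(EvaluationError):
            sc.extract_profile(vol, (0.0, 50.0, 5.0), "LR")

    def test_pbt_plateau_matches_material(self, small_baseline):
        spec = [s for s in sc.measurement_specs(small_phantom_spec(False)) if s.name == "pbt"][0]
        prof = sc.extract_profile(small_baseline, spec.center, "LR", spec.profile_half_mm["LR"])
        plateau = np.median(prof.values_hu[len(prof.values_hu) // 3 : -len(prof.values_hu) // 3])
        assert plateau == pytest.approx(693.0, abs=3.0)

    def test_profile_needs_at_least_eight_samples(self):
        with pytest.raises(EvaluationError):
            profile_from([1.0, 2.0, 3.0])


class TestFwhm:
    def test_rectangle_width_recovered(self):
        # edges midway between samples: the generic sub-voxel case
        assert sc.fwhm(rect_profile(10.0, center=0.25)) == pytest.approx(10.0, abs=0.25)

    def test_triangle_half_max_is_half_base(self):
        pos = np.arange(-20.0, 20.0 + 0.25, 0.5)
        vals = np.clip(1.0 - np.abs(pos) / 10.0, 0.0, None) * 200.0
        assert sc.fwhm(Profile(pos, vals), plateau_mode="peak") == pytest.approx(10.0, abs=0.01)

    def test_gaussian_fwhm_closed_form(self):
        sigma = 2.0
        pos = np.arange(-10.0, 10.0 + 0.05, 0.1)
        vals = 150.0 * np.exp(-0.5 * (pos / sigma) ** 2)
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma  # 4.71 mm
        assert sc.fwhm(Profile(pos, vals), plateau_mode="peak") == pytest.approx(expected, abs=0.05)

    def test_dip_structures_measured_like_peaks(self):
        prof = rect_profile(12.0, high=-758.0, low=-36.0, center=0.25)
        assert sc.fwhm(prof) == pytest.approx(12.0, abs=0.25)

    def test_profile_without_structure_raises(self):
        flat = profile_from(np.full(32, 40.0))
        with pytest.raises(EvaluationError):
            sc.fwhm(flat)

    def test_one_sided_structure_raises(self):
        step = np.where(np.arange(32) < 10, 0.0, 100.0)  # no right edge
        with pytest.raises(EvaluationError):
            sc.fwhm(profile_from(step))

    @settings(deadline=None, max_examples=25)
    @given(
        shift=st.floats(-5.0, 5.0),
        scale=st.floats(0.5, 3.0),
        width=st.floats(6.0, 18.0),
    )
    def test_translation_invariance_and_scale_equivariance(self, shift, scale, width):
        """fwhm ignores translation and scales linearly with the coordinates."""
        base = rect_profile(width)
        w0 = sc.fwhm(base)
        shifted = Profile(base.positions_mm + shift, base.values_hu)
        scaled = Profile(base.positions_mm * scale, base.values_hu)
        assert sc.fwhm(shifted) == pytest.approx(w0, abs=1e-9)
        assert sc.fwhm(scaled) == pytest.approx(w0 * scale, rel=1e-9)


class TestRoiStats:
    def test_uniform_region(self):
        vol = sc.Volume(np.full((6, 6, 6), 693.0))
        roi = sc.RoiSpec("u", "box", (2.5, 2.5, 2.5), (4.0, 4.0, 4.0))
        assert sc.roi_stats(vol, roi) == (693.0, 0.0)

    def test_two_voxel_population_sd(self):
        vol = sc.Volume(np.array([[[0.0, 100.0]]]))
        roi = sc.RoiSpec("pair", "box", (0.5, 0.0, 0.0), (2.0, 0.5, 0.5))
        mean, sd = sc.roi_stats(vol, roi)
        assert (mean, sd) == (50.0, 50.0)  # population convention (divisor n)

    def test_empty_roi_rejected(self):
        vol = sc.Volume(np.zeros((4, 4, 4)))
        roi = sc.RoiSpec("nowhere", "box", (100.0, 100.0, 100.0), (0.5, 0.5, 0.5))
        with pytest.raises(EvaluationError):
            sc.roi_stats(vol, roi)

    def test_margin_must_leave_interior(self):
        with pytest.raises(EvaluationError):
            sc.RoiSpec.from_structure("thin", "box", (0, 0, 0), (3.0, 3.0, 3.0), 2.0)

    def test_solid_water_baseline(self, small_baseline):
        spec = [s for s in sc.measurement_specs(small_phantom_spec(False))
                if s.name == "solid_water"][0]
        mean, sd = sc.roi_stats(small_baseline, spec.roi)
        assert mean == pytest.approx(29.0, abs=2.0)
        assert sd < 2.0


class TestTrendFit:
    def test_exact_line_recovered(self):
        x = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        fit = sc.trend_fit(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.slope_pvalue < 1e-6

    def test_constant_response(self):
        x = np.array([5.0, 10.0, 15.0, 20.0])
        fit = sc.trend_fit(x, np.full(4, 3.25))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.slope_ci[0] <= 0.0 <= fit.slope_ci[1]
        assert fit.slope_pvalue > 0.05

    def test_matches_textbook_ols_formulas(self, rng):
        """Closed-form OLS oracle: slope, intercept, CI and p to 1e-10."""
        x = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        y = rng.normal(0.0, 1.0, size=6)
        n = x.size
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - (intercept + slope * x)
        s2 = np.sum(resid**2) / (n - 2)
        se_slope = np.sqrt(s2 / sxx)
        tval = slope / se_slope
        p = 2.0 * stats.t.sf(abs(tval), df=n - 2)
        tc = stats.t.ppf(0.975, df=n - 2)
        fit = sc.trend_fit(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.slope_pvalue == pytest.approx(p, abs=1e-10)
        assert fit.slope_ci[0] == pytest.approx(slope - tc * se_slope, abs=1e-8)
        assert fit.slope_ci[1] == pytest.approx(slope + tc * se_slope, abs=1e-8)

    def test_measurement_floor_widens_uncertainty(self):
        x = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        y = np.array([-0.11, -0.09, 0.0, 0.0, 0.0, 0.0])
        plain = sc.trend_fit(x, y)
        floored = sc.trend_fit(x, y, measurement_sd=0.33)
        assert floored.slope == pytest.approx(plain.slope, abs=1e-12)
        assert floored.slope_pvalue > plain.slope_pvalue

    def test_needs_three_distinct_angles(self):
        with pytest.raises(EvaluationError):
            sc.trend_fit([5.0, 5.0, 10.0], [1.0, 2.0, 3.0])


class TestDistortionReport:
    def test_self_comparison_is_identically_zero(self, small_baseline):
        structures = sc.measurement_specs(small_phantom_spec(False))
        report = sc.distortion_report(small_baseline, {0.0: small_baseline}, structures)
        assert np.all(report.distortion["distortion_mm"].to_numpy() == 0.0)
        assert np.all(report.hu["diff_hu"].to_numpy() == 0.0)
        assert all(v == 0.0 for v in report.direction_averages().values())

    def test_uncorrected_tilted_scan_shows_ap_elongation(self, small_metal_phantom):
        """A raw 25° scan, compared as-is, is elongated along AP only."""
        tilted = sc.simulate_tilted_scan(small_metal_phantom, 25.0).with_tilt(0.0)
        body = [s for s in sc.measurement_specs(small_phantom_spec(True)) if s.name == "body"][0]
        p0 = sc.extract_profile(small_metal_phantom, body.center, "AP")
        p1 = sc.extract_profile(tilted, body.center, "AP")
        assert sc.fwhm(p1) - sc.fwhm(p0) > 5.0

    def test_report_covers_all_structures_directions_angles(self, small_study):
        df = small_study.report.distortion
        assert len(df) == 6 * 3 * len(small_study.config.angles)
        assert set(df["direction"]) == {"AP", "LR", "SI"}
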