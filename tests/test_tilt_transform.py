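"""Affine factors, shear/scale untilting and forward-model consistency."""

import math

import numpy as np
import pytest
from scipy import ndimage

import stereoct as sc
from stereoct.errors import TransformError
from stereoct.tilt import FACTOR_TABLE

from conftest import SMALL_SPACING, small_phantom_spec

CALIBRATION_GRID = (0.55, 0.55, 2.5)


class TestFactors:
    @pytest.mark.parametrize(
        "angle,shear,scale", [(25.0, 0.092, 0.905), (5.0, 0.019, 0.999), (-25.0, 0.092, 0.905)]
    )
    def test_table_values(self, angle, shear, scale):
        f = sc.get_tilt_factors(angle, source="table")
        assert f.shear == shear
        assert f.scale_y == scale

    def test_zero_angle_is_identity(self):
        for source in ("table", "geometric"):
            f = sc.get_tilt_factors(0.0, source=source, spacing=CALIBRATION_GRID)
            assert (f.shear, f.scale_y) == (0.0, 1.0)

    def test_angle_outside_table_domain_rejected(self):
        with pytest.raises(TransformError, match="valid"):
            sc.get_tilt_factors(12.0, source="table")
        with pytest.raises(TransformError):
            sc.get_tilt_factors(35.0, source="geometric", spacing=CALIBRATION_GRID)

    def test_geometric_matches_closed_form(self):
        f = sc.get_tilt_factors(25.0, source="geometric", spacing=CALIBRATION_GRID)
        assert f.scale_y == pytest.approx(math.cos(math.radians(25.0)), abs=1e-12)
        assert f.shear == pytest.approx(math.sin(math.radians(25.0)) * 0.55 / 2.5, abs=1e-12)

    def test_geometric_source_tracks_published_table(self):
        """cos θ / sin θ·dy/dz reproduce the empirical table to ≲ 0.005."""
        for angle, (shear, scale) in FACTOR_TABLE.items():
            g = sc.get_tilt_factors(angle, source="geometric", spacing=CALIBRATION_GRID)
            assert abs(g.scale_y - scale) <= 0.006
            assert abs(g.shear - shear) <= 0.006

    def test_custom_table_overrides_builtin(self):
        f = sc.get_tilt_factors(25.0, source="table", table={25: (0.1, 0.9)})
        assert (f.shear, f.scale_y) == (0.1, 0.9)
        spec = sc.TransformSpec(source="table", factor_table=((25, (0.1, 0.9)),))
        assert spec.table() == {25: (0.1, 0.9)}

    def test_table_shear_monotone_with_angle(self):
        shears = [FACTOR_TABLE[a][0] for a in sorted(FACTOR_TABLE)]
        assert all(b >= a for a, b in zip(shears, shears[1:]))


def uniform_volume(value=0.0, shape=(40, 40, 8), spacing=(1.0, 1.0, 1.0), tilt=0.0):
    return sc.Volume(np.full(shape, value), spacing=spacing, tilt_angle_deg=tilt)


class TestShear:
    def test_zero_shear_is_identity(self):
        vol = uniform_volume()
        vol.voxels[20, 10, 4] = 1000.0
        out = sc.shear_untilt(vol, sc.AffineFactors(0.0, 0.0, 1.0), angle_deg=0.0)
        assert np.array_equal(out.voxels, vol.voxels)

    @pytest.mark.parametrize("angle,dy_off", [(25.0, 12), (25.0, -8), (-25.0, 12)])
    def test_point_moves_across_slices_proportionally_to_ap_offset(self, angle, dy_off):
        """A bright voxel at AP offset Δy shifts Δz = s·Δy slices (sign mirrors tilt)."""
        shear = 0.25
        vol = uniform_volume(shape=(40, 41, 9), tilt=angle)
        yc = (vol.shape[1] - 1) / 2
        z0, y0 = 20, int(yc) + dy_off
        vol.voxels[z0, y0, 4] = 1000.0
        out = sc.shear_untilt(vol, sc.AffineFactors(abs(angle), shear, 1.0), angle_deg=angle)
        bright = np.clip(out.voxels, 0.0, None)  # ignore the out-of-field fill
        zc_out = ndimage.center_of_mass(bright)[0]
        expected = z0 + np.sign(angle) * shear * (y0 - yc)
        assert zc_out == pytest.approx(expected, abs=0.05)

    def test_parallel_lines_stay_parallel(self):
        """Two parallel oblique bright segments stay parallel to within 0.1°."""
        vol = uniform_volume(shape=(60, 60, 3))
        for y in range(10, 50):
            z = 15 + (y - 10) // 2
            vol.voxels[z, y, 0] = 1000.0  # one line per x-plane
            vol.voxels[z, y, 2] = 1000.0

        def direction(plane_mask):
            pts = np.argwhere(plane_mask).astype(float)
            pts -= pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts, full_matrices=False)
            return vt[0]

        out = sc.shear_untilt(vol, sc.AffineFactors(25.0, 0.3, 1.0), angle_deg=25.0)
        d1 = direction(out.voxels[:, :, 0] > 400)
        d2 = direction(out.voxels[:, :, 2] > 400)
        angle = math.degrees(math.acos(min(1.0, abs(float(np.dot(d1, d2))))))
        assert angle <= 0.1


class TestScale:
    def test_unit_scale_is_identity(self):
        vol = uniform_volume()
        vol.voxels[:, 15:25, :] = 500.0
        out = sc.scale_y(vol, sc.AffineFactors(0.0, 0.0, 1.0))
        assert np.array_equal(out.voxels, vol.voxels)

    def test_rectangle_ap_width_scales_by_factor(self):
        """A 40 mm AP slab scaled by 0.905 measures 36.2 mm FWHM ± one voxel."""
        vol = sc.Volume(np.full((8, 120, 8), -1000.0), spacing=(1.0, 1.0, 1.0))
        yc = (vol.shape[1] - 1) / 2
        vol.voxels[:, int(yc - 20) : int(yc + 20), :] = 0.0
        out = sc.scale_y(vol, sc.AffineFactors(25.0, 0.092, 0.905))
        prof = sc.extract_profile(out, (4.0, yc, 4.0), "AP")
        assert sc.fwhm(prof) == pytest.approx(36.2, abs=1.0)

    def test_scale_round_trip_preserves_interior_mean(self):
        """Scale then inverse-scale keeps a piecewise-constant interior within 2 HU."""
        vol = sc.Volume(np.full((8, 80, 8), -36.0), spacing=(1.0, 1.0, 1.0))
        vol.voxels[:, 25:55, :] = 693.0
        down = sc.scale_y(vol, sc.AffineFactors(25.0, 0.0, 0.905))
        recovered = _scale_by(down, 1 / 0.905)
        roi = sc.RoiSpec("slab", "box", (4.0, 39.5, 4.0), (4.0, 20.0, 4.0))
        mean0, _ = sc.roi_stats(vol, roi)
        mean1, _ = sc.roi_stats(recovered, roi)
        assert abs(mean1 - mean0) <= 2.0

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(TransformError):
            sc.AffineFactors(10.0, 0.0, 0.0)


def _scale_by(volume, factor):
    """Direct inverse-mapping AP scaling used as a round-trip helper."""
    ny = volume.shape[1]
    yc = (ny - 1) / 2
    m = np.eye(3)
    m[1, 1] = 1 / factor
    offset = np.array([0.0, yc * (1 - 1 / factor), 0.0])
    out = ndimage.affine_transform(
        volume.voxels, m, offset=offset, order=1, mode="constant", cval=-1000.0, prefilter=False
    )
    return volume.with_voxels(out)


class TestUntilt:
    def test_untilt_of_axial_volume_is_identity(self):
        vol = uniform_volume(value=100.0, tilt=0.0)
        out = sc.untilt(vol)
        assert out.tilt_angle_deg == 0.0
        assert np.array_equal(out.voxels, vol.voxels)

    @pytest.mark.parametrize("angle", sorted(FACTOR_TABLE))
    def test_forward_then_untilt_recovers_phantom(self, small_baseline, angle):
        """Round trip at every table angle: interior ROI means within 2 HU."""
        spec = sc.TransformSpec(source="geometric")
        tilted = sc.apply_tilt(small_baseline, float(angle), spec)
        assert tilted.tilt_angle_deg == angle
        recovered = sc.untilt(tilted, spec)
        assert recovered.tilt_angle_deg == 0.0
        for m in sc.measurement_specs(small_phantom_spec(amalgam=False)):
            m0, _ = sc.roi_stats(small_baseline, m.roi)
            m1, _ = sc.roi_stats(recovered, m.roi)
            assert abs(m1 - m0) <= 2.0, m.name

    def test_round_trip_plug_fwhm_within_one_voxel(self, small_baseline):
        spec = sc.TransformSpec(source="geometric")
        recovered = sc.untilt(sc.apply_tilt(small_baseline, 25.0, spec), spec)
        for m in sc.measurement_specs(small_phantom_spec(amalgam=False)):
            if m.name == "body":
                continue
            for d in ("AP", "LR"):
                p0 = sc.extract_profile(small_baseline, m.center, d, m.profile_half_mm[d])
                p1 = sc.extract_profile(recovered, m.center, d, m.profile_half_mm[d])
                assert abs(sc.fwhm(p1) - sc.fwhm(p0)) <= SMALL_SPACING[0], (m.name, d)

    def test_round_trip_blur_grows_toward_extreme_angles(self, small_baseline):
        """Interpolation blur at the largest tilt exceeds that at the smallest.

        The per-angle RMS is not strictly monotone — it depends on the
        fractional alignment of the sheared sampling lattice — but larger
        shears smear more overall.
        """
        spec = sc.TransformSpec(source="geometric")
        rms = {}
        for angle in (5, 30):
            rec = sc.untilt(sc.apply_tilt(small_baseline, float(angle), spec), spec)
            rms[angle] = float(np.sqrt(((rec.voxels - small_baseline.voxels) ** 2).mean()))
        assert 0.0 < rms[5] <= rms[30], rms

    def test_two_step_untilt_close_to_single_resample(self, small_baseline):
        one = sc.untilt(sc.apply_tilt(small_baseline, 20.0), sc.TransformSpec())
        two = sc.untilt(
            sc.apply_tilt(small_baseline, 20.0), sc.TransformSpec(single_resample=False)
        )
        # same affine, one vs two interpolations: small extra blur only
        assert np.abs(one.voxels - two.voxels).mean() < 10.0

    def test_untilt_matches_simpleitk_resampler(self):
        """Independent oracle: SimpleITK resampling under the same affine."""
        sitk = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(7)
        vox = rng.uniform(-1000, 1000, size=(24, 30, 5))
        vol = sc.Volume(vox, spacing=(1.0, 1.0, 1.0), tilt_angle_deg=25.0)
        ours = sc.untilt(vol, sc.TransformSpec(source="geometric"))

        theta = math.radians(25.0)
        s, c = math.sin(theta), math.cos(theta)
        img = sitk.GetImageFromArray(vox)  # (z, y, x) -> sitk (x, y, z)
        tf = sitk.AffineTransform(3)
        tf.SetMatrix([1, 0, 0, 0, 1 / c, 0, 0, -s / c, 1])
        nz, ny, nx = vox.shape
        tf.SetCenter(((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2))
        res = sitk.Resample(img, img, tf, sitk.sitkLinear, -1000.0)
        theirs = sitk.GetArrayFromImage(res)
        # compare away from the volume border, where out-of-field edge
        # conventions differ between the two resamplers
        crop = (slice(6, 18), slice(8, 22), slice(None))
        assert np.abs(ours.voxels[crop] - theirs[crop]).max() < 1e-6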