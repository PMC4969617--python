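import numpy as np
import pytest

from nanoheat.exceptions import (DetectionError, FootprintError,
                                 ValidationError)
from nanoheat.footprint import (MicroscopyFrame, RadialProfile, analyze_frame,
                                annulus_background, locate_center,
                                measure_background, melting_radius,
                                radial_profile)
from nanoheat.synthetic import FootprintScene, make_footprint_frame

from .oracles import rotate_about


def _frame(fluor, refl=None, px=0.1, intensity=1e6):
    return MicroscopyFrame(fluorescence=fluor, reflection=refl,
                           pixel_size_um=px, intensity_W_per_cm2=intensity)


class TestLocateCenter:
    def test_single_bright_pixel(self):
        img = np.zeros((40, 40))
        img[20, 10] = 50.0  # row 20, column 10
        assert locate_center(_frame(img, img)) == (10.0, 20.0)

    def test_gaussian_spot_subpixel(self):
        scene = FootprintScene(center_xy=(32.5, 17.25), shape=(64, 64),
                               d_m_um=1.0)
        frame, truth = make_footprint_frame(scene)
        x, y = locate_center(frame)
        assert abs(x - 32.5) < 0.05 and abs(y - 17.25) < 0.05

    def test_uniform_image_is_detection_error(self):
        with pytest.raises(DetectionError):
            locate_center(_frame(np.full((32, 32), 7.0), np.full((32, 32), 7.0)))

    def test_fluorescence_fallback_warns(self):
        img = np.zeros((32, 32))
        img[16, 16] = 10.0
        with pytest.warns(UserWarning, match="reflection"):
            locate_center(_frame(img))


class TestRadialProfile:
    def test_uniform_image_gives_flat_profile(self):
        prof = radial_profile(_frame(np.full((64, 64), 3.5), px=0.05),
                              center=(31.5, 31.5))
        np.testing.assert_allclose(prof.mean_intensity, 3.5)

    def test_perfect_disk_levels(self):
        h = w = 101
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(xx - 50, yy - 50) * 0.1
        img = np.where(r <= 2.0, 2.0, 1.0)
        prof = radial_profile(_frame(img, px=0.1), center=(50.0, 50.0))
        bw = 0.1
        inside = prof.bin_centers_um < 2.0 - bw
        outside = (prof.bin_centers_um > 2.0 + bw) & (prof.bin_centers_um < 4.5)
        np.testing.assert_allclose(prof.mean_intensity[inside], 2.0)
        np.testing.assert_allclose(prof.mean_intensity[outside], 1.0)

    def test_quarter_turn_rotation_leaves_profile_unchanged(self):
        frame, _ = make_footprint_frame(FootprintScene(center_xy=(128.0, 128.0)))
        rot = np.rot90(frame.fluorescence, 2)  # 180 deg about the center pixel
        p1 = radial_profile(frame, (128.0, 128.0))
        p2 = radial_profile(_frame(rot, px=frame.pixel_size_um), (127.0, 127.0))
        np.testing.assert_allclose(p1.mean_intensity, p2.mean_intensity,
                                   rtol=1e-12)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            radial_profile(_frame(np.ones((16, 16))), center=(20.0, 5.0))


class TestBackground:
    def test_constant_region(self):
        img = np.full((64, 64), 100.0)
        assert measure_background(_frame(img), (0, 10, 0, 10)) == 100.0

    def test_gaussian_noise_mean_within_clt_bound(self):
        rng = np.random.default_rng(7)
        img = np.clip(rng.normal(100.0, 5.0, (100, 100)), 0, None)
        bg = measure_background(_frame(img), (0, 100, 0, 100))
        assert abs(bg - 100.0) < 3.0 * 5.0 / 100.0  # 3 sigma / sqrt(n)

    def test_roi_inside_melted_zone_rejected(self):
        img = np.full((64, 64), 100.0)
        with pytest.raises(ValidationError, match="overlaps"):
            measure_background(_frame(img, px=0.1), (28, 36, 28, 36),
                               center=(32.0, 32.0), expected_d_m_um=2.0)

    def test_annulus_background_on_flat_field(self):
        img = np.full((128, 128), 42.0)
        assert annulus_background(_frame(img), (63.5, 63.5)) == 42.0


class TestMeltingRadius:
    @staticmethod
    def _profile(values, bw=0.1):
        values = np.asarray(values, float)
        centers = (np.arange(len(values)) + 0.5) * bw
        return RadialProfile(centers, values, np.ones(len(values), int))

    def test_step_profile_threshold_and_radius(self):
        bw = 0.1
        vals = np.where((np.arange(40) + 0.5) * bw <= 2.0, 200.0, 100.0)
        d_m, tr, mmax, flag = melting_radius(self._profile(vals), 100.0)
        assert tr == 150.0
        # crossing interpolated halfway between the last high bin (1.95)
        # and the first low bin (2.05)
        assert d_m == pytest.approx(2.0, abs=bw / 2)
        assert not flag

    def test_monotone_profile_above_threshold_is_error(self):
        vals = np.linspace(300.0, 200.0, 30)  # never below Tr ~ 200
        with pytest.raises(FootprintError, match="exceeds"):
            melting_radius(self._profile(vals), 100.0)

    def test_profile_below_background_is_error(self):
        with pytest.raises(FootprintError, match="background"):
            melting_radius(self._profile(np.full(20, 50.0)), 100.0)

    def test_diffraction_flag_for_tiny_footprint(self):
        bw = 0.02
        r = (np.arange(50) + 0.5) * bw
        vals = np.where(r <= 0.1, 200.0, 100.0)
        d_m, _, _, flag = melting_radius(self._profile(vals, bw), 100.0,
                                         psf_sigma_um=0.073)
        assert flag  # footprint below twice the PSF width


class TestAnalyzeFrame:
    def test_round_trip_on_synthetic_frame(self):
        frame, truth = make_footprint_frame(FootprintScene())
        m = analyze_frame(frame)
        assert m.d_m_um == pytest.approx(truth["d_m_um"], rel=0.02)
        assert m.background < m.threshold < m.melted_max

    def test_affine_intensity_invariance(self):
        frame, _ = make_footprint_frame(FootprintScene())
        gain, offset = 3.7, 11.0
        rescaled = MicroscopyFrame(
            fluorescence=gain * frame.fluorescence + offset,
            reflection=gain * frame.reflection + offset,
            pixel_size_um=frame.pixel_size_um,
            intensity_W_per_cm2=frame.intensity_W_per_cm2)
        m0 = analyze_frame(frame)
        m1 = analyze_frame(rescaled)
        assert m1.d_m_um == pytest.approx(m0.d_m_um, abs=1e-9)

    def test_rotation_invariance_within_half_pixel(self):
        scene = FootprintScene(center_xy=(128.0, 128.0))
        frame, truth = make_footprint_frame(scene)
        rot = MicroscopyFrame(
            fluorescence=rotate_about(frame.fluorescence, (128.0, 128.0), 37.0),
            reflection=rotate_about(frame.reflection, (128.0, 128.0), 37.0),
            pixel_size_um=frame.pixel_size_um,
            intensity_W_per_cm2=frame.intensity_W_per_cm2)
        m0 = analyze_frame(frame)
        m1 = analyze_frame(rot)
        assert abs(m1.d_m_um - m0.d_m_um) <= 0.5 * frame.pixel_size_um

    def test_blank_frame_raises_stage_tagged_detection_error(self):
        blank = _frame(np.full((64, 64), 5.0), np.full((64, 64), 5.0))
        with pytest.raises(DetectionError, match="locate_center"):
            analyze_frame(blank)

    def test_psf_bias_grows_as_footprint_approaches_diffraction_limit(self):
        # in the diffraction-limited regime (D_m <= twice the PSF
        # width) the recovered radius is biased upward, increasingly so
        # as the true footprint shrinks — the flag marks exactly this
        sigma = 0.15
        biases, flags = [], []
        for d_m in (0.30, 0.25, 0.20, 0.15):
            frame, truth = make_footprint_frame(
                FootprintScene(d_m_um=d_m, psf_sigma_um=sigma))
            m = analyze_frame(frame, psf_sigma_um=sigma)
            biases.append((m.d_m_um - d_m) / d_m)
            flags.append(m.diffraction_limited)
        assert all(flags)
        assert all(b2 > b1 for b1, b2 in zip(biases, biases[1:]))
        assert biases[-1] > 0.1  # strongly overestimated at D_m ~ PSF
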