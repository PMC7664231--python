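"""Generator contracts: planted signals, determinism, quantization."""

import numpy as np
import pytest

from sheepvitals.synthetic import (Occluder, SceneSpec, ThermalSceneSpec,
                                   generate_cohort, generate_rgb_scene,
                                   generate_thermal_scene, RR_CLASS_RANGES,
                                   SNR_PRESETS)

from conftest import make_scene


class TestRGBScene:
    def test_no_signal_no_noise_frames_identical(self):
        spec = make_scene(amp_hr=0, amp_rr=0, noise_sd=0, n_frames=40)
        stack, _ = generate_rgb_scene(spec)
        assert (stack.frames == stack.frames[0]).all()

    def test_green_roi_mean_has_planted_dominant_frequency(self):
        # independent oracle: plain FFT of the emitted ROI-mean series
        spec = make_scene(hr_hz=1.5, n_frames=1800, noise_sd=1.0)
        stack, truth = generate_rgb_scene(spec)
        x, y, w, h = spec.roi_true
        series = stack.frames[:, y:y + h, x:x + w, 1].reshape(1800, -1).mean(axis=1)
        series = series - series.mean()
        mags = np.abs(np.fft.rfft(series))
        freqs = np.fft.rfftfreq(1800, d=1.0 / spec.fps)
        mask = freqs > 0.2
        assert freqs[mask][np.argmax(mags[mask])] == pytest.approx(1.5, abs=0.02)

    def test_occluder_fraction_bookkeeping(self):
        x, y, w, h = (14, 9, 20, 16)
        bar = Occluder(x=x + 2, width=6, frame_start=5, frame_end=15)
        spec = make_scene(n_frames=20, occluders=(bar,), noise_sd=0)
        stack, truth = generate_rgb_scene(spec)
        frac = truth["occluded_fraction"]
        assert frac[0] == 0.0
        assert frac[10] == pytest.approx(6 / 20)
        assert frac[19] == 0.0
        assert (stack.frames[10, :, x + 2:x + 8, :] == bar.value).all()

    def test_nyquist_violation_names_frequency(self):
        with pytest.raises(ValueError, match="rr_hz=20"):
            make_scene(rr_hz=20.0).validate()

    def test_motion_keeps_roi_and_truth_boxes(self):
        spec = make_scene(n_frames=20, motion=(0.5, 0.0), noise_sd=0)
        stack, truth = generate_rgb_scene(spec)
        assert truth["roi"].shape == (20, 4)
        # cumulative translation: 19 steps of 0.5 px, rounded boxes
        assert truth["roi"][-1, 0] - truth["roi"][0, 0] == pytest.approx(9.5, abs=1.0)

    def test_roi_escaping_frame_rejected(self):
        with pytest.raises(ValueError, match="frame bounds"):
            make_scene(n_frames=200, motion=(1.0, 0.0)).validate()

    def test_determinism_bit_identical(self):
        spec = make_scene(n_frames=25)
        a, _ = generate_rgb_scene(spec)
        b, _ = generate_rgb_scene(spec)
        assert (a.frames == b.frames).all()

    def test_quantization_dither_preserves_subunit_amplitude(self):
        # with amp >= 1 DN and noise >= 0.5 DN, the planted peak stands
        # >= 10x above the median off-peak magnitude
        spec = make_scene(amp_hr=1.0, noise_sd=0.5, hr_hz=1.5, n_frames=1800,
                          seed=21)
        stack, _ = generate_rgb_scene(spec)
        x, y, w, h = spec.roi_true
        series = stack.frames[:, y:y + h, x:x + w, 1].reshape(1800, -1).mean(axis=1)
        mags = np.abs(np.fft.rfft(series - series.mean()))
        freqs = np.fft.rfftfreq(1800, d=1 / 30.0)
        peak = mags[np.argmin(np.abs(freqs - 1.5))]
        off = np.median(mags[(freqs > 0.3) & (np.abs(freqs - 1.5) > 0.2)])
        assert peak > 10 * off


class TestThermalScene:
    def test_constant_peak_is_exact_roi_max(self):
        spec = ThermalSceneSpec(hotspot_peak_c=38.5, noise_sd_c=0, n_frames=10)
        stack, truth = generate_thermal_scene(spec)
        x, y, w, h = spec.roi_true
        for frame in stack.frames:
            assert frame[y:y + h, x:x + w].max() == pytest.approx(38.5, abs=1e-9)

    def test_linear_trajectory_mean_of_maxima(self):
        peaks = np.linspace(35.0, 40.0, 540)
        spec = ThermalSceneSpec(hotspot_peak_c=peaks, noise_sd_c=0, n_frames=540)
        stack, _ = generate_thermal_scene(spec)
        x, y, w, h = spec.roi_true
        maxima = stack.frames[:, y:y + h, x:x + w].reshape(540, -1).max(axis=1)
        assert maxima.mean() == pytest.approx(37.5, abs=1e-9)

    def test_background_only_roi_max_bounded_by_noise(self):
        spec = ThermalSceneSpec(hotspot_sigma=0, background_c=20.0,
                                noise_sd_c=0.5, n_frames=30, seed=3)
        stack, _ = generate_thermal_scene(spec)
        x, y, w, h = spec.roi_true
        maxima = stack.frames[:, y:y + h, x:x + w].reshape(30, -1).max(axis=1)
        assert np.all(np.abs(maxima - 20.0) <= 4 * 0.5)

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ThermalSceneSpec(roi_true=(70, 0, 32, 28)).validate()

    def test_cold_hotspot_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            ThermalSceneSpec(hotspot_peak_c=15.0, background_c=20.0).validate()

    def test_csv_round_trip(self, tmp_path):
        from sheepvitals.thermal import read_thermal_stack
        spec = ThermalSceneSpec(n_frames=4, noise_sd_c=0.2, seed=5)
        stack, _, out = generate_thermal_scene(spec, out_dir=tmp_path / "th")
        back = read_thermal_stack(out)
        assert back.fps == spec.fps
        np.testing.assert_allclose(back.frames, stack.frames, atol=1e-4)


class TestCohort:
    def test_balanced_bands_and_count(self):
        cohort = generate_cohort(134, seed=0)
        assert len(cohort) == 134
        counts = {b: sum(s.band == b for s in cohort) for b in RR_CLASS_RANGES}
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_frequency_ranges(self):
        cohort = generate_cohort(60, seed=2)
        for s in cohort:
            lo, hi = RR_CLASS_RANGES[s.band]
            assert lo <= s.rr_hz <= hi
            assert 0.2 <= s.rr_hz <= 3.2
            assert 1.05 <= s.hr_hz <= 2.2

    def test_reference_labels_are_60x_frequency(self):
        cohort = generate_cohort(6, seed=3)
        for s in cohort:
            assert s.rr_brpm == pytest.approx(60 * s.rr_hz)
            assert s.hr_bpm == pytest.approx(60 * s.hr_hz)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cohort(10, band_mix=(0.5, 0.5, 0.5))

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="preset"):
            generate_cohort(10, snr="ultra")

    def test_presets_set_noise(self):
        for name, sd in SNR_PRESETS.items():
            cohort = generate_cohort(3, seed=1, snr=name)
            assert all(s.spec.noise_sd == sd for s in cohort)
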