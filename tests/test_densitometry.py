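"""Flat-field correction, wedge calibration, and transect extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralchron import densitometry, synthgen
from coralchron.densitometry import (CalibrationCurve, CoreImage, WedgeStandard,
                                     extract_transect, fit_wedge_calibration,
                                     flat_field_correct, validate_calibration)


class TestFlatField:
    def test_uniform_plate_is_identity(self):
        img = CoreImage(np.full((40, 60), 1234.0), 16, 0.005)
        plate = CoreImage(np.full((40, 60), 4000.0), 16, 0.005)
        out = flat_field_correct(img, plate)
        assert np.abs(out.pixels - img.pixels).max() <= 1.0

    def test_known_gradient_divided_out(self):
        # oracle: elementwise division on the generating arrays
        rng = np.random.default_rng(5)
        clean = rng.uniform(5000, 30000, size=(50, 70))
        gradient = synthgen._gradient_field((50, 70), 0.1)
        img = CoreImage(clean * gradient, 16, 0.005)
        plate_lum = 40000.0 * gradient
        plate = CoreImage(plate_lum, 16, 0.005)
        out = flat_field_correct(img, plate, smooth_sigma=0)
        expected = (clean * gradient) / (plate_lum / plate_lum.mean())
        assert np.allclose(out.pixels, expected, atol=1e-6)

    def test_mean_luminance_preserved(self):
        rng = np.random.default_rng(0)
        clean = rng.uniform(10000, 30000, size=(64, 64))
        gradient = synthgen._gradient_field((64, 64), 0.1)
        img = CoreImage(clean * gradient, 16, 0.005)
        plate = CoreImage(45000.0 * gradient, 16, 0.005)
        out = flat_field_correct(img, plate, smooth_sigma=0)
        assert out.pixels.mean() == pytest.approx(img.pixels.mean(), rel=0.01)

    def test_shape_mismatch_rejected(self):
        img = CoreImage(np.ones((10, 10)), 16, 0.005)
        plate = CoreImage(np.ones((10, 12)), 16, 0.005)
        with pytest.raises(ValueError, match="shape"):
            flat_field_correct(img, plate)

    def test_zero_plate_pixels_rejected_with_guidance(self):
        img = CoreImage(np.ones((10, 10)), 16, 0.005)
        plate = CoreImage(np.zeros((10, 10)), 16, 0.005)
        with pytest.raises(ValueError, match="smooth"):
            flat_field_correct(img, plate)

    def test_correction_removes_calibration_bias_from_gradient(self, true_curve):
        # a 10% beam gradient biases the predicted standard density; dividing
        # by the plate brings the prediction back within 1%
        spec = WedgeStandard()
        scene = synthgen.SceneSpec(pixel_size=0.01, beam_gradient_amp=0.1,
                                   grayscale_noise_sd=0.0, seed=2)
        wedge = synthgen.gen_wedge_image(true_curve, spec, scene)
        plate = synthgen.gen_background_plate(scene, wedge.shape)
        n_wedge = int(round(spec.length / 0.01))
        h, w = wedge.shape
        transect = [(2.0, h / 2.0), (n_wedge - 3.0, h / 2.0)]
        air = (n_wedge + 5, 2, w - 3, h - 3)

        raw_curve = fit_wedge_calibration(wedge, spec, transect, air)
        corr_curve = fit_wedge_calibration(flat_field_correct(wedge, plate),
                                           spec, transect, air)
        # the corrected image is uniformly rescaled by the plate mean gain, so
        # predictions must be made in the same corrected frame
        gain = np.asarray(synthgen._gradient_field(wedge.shape, 0.1)).mean()
        std_raw = true_curve.luminance(2.93)  # standard imaged at gradient==1
        err_raw = abs(raw_curve.density(std_raw) - 2.93) / 2.93
        err_corr = abs(corr_curve.density(std_raw * gain) - 2.93) / 2.93
        assert err_corr < 0.01
        assert err_raw > err_corr


class TestCalibrationCurve:
    def test_two_point_exact_fit(self):
        curve = CalibrationCurve.from_points([200.0, 50.0], [0.0, 2.71])
        assert curve.slope == pytest.approx(-2.71 / 150.0)
        assert curve.density(200.0) == pytest.approx(0.0, abs=1e-12)
        assert curve.density(50.0) == pytest.approx(2.71)

    @given(a=st.floats(0, 1), l1=st.floats(100, 1000), l2=st.floats(100, 1000))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_luminance(self, a, l1, l2):
        curve = CalibrationCurve(slope=-5e-5, intercept=3.0)
        mix = a * l1 + (1 - a) * l2
        assert curve.density(mix) == pytest.approx(
            a * curve.density(l1) + (1 - a) * curve.density(l2), abs=1e-9)

    def test_json_round_trip(self, tmp_path):
        curve = CalibrationCurve(slope=-5.2e-5, intercept=3.224, fit_r2=0.999,
                                 n_points=500, density_range=(0.0, 0.11))
        curve.to_json(tmp_path / "c.json", provenance={"wedge": "w.tif"})
        back = CalibrationCurve.from_json(tmp_path / "c.json")
        assert back.slope == curve.slope
        assert back.density_range == curve.density_range


class TestWedgeCalibration:
    def test_recovered_slope_within_1pct_at_noise_half(self, true_curve):
        # oracle: the generating slope; >= 500 samples, seed 11
        spec = WedgeStandard()
        scene = synthgen.SceneSpec(pixel_size=0.01, grayscale_noise_sd=0.5, seed=11)
        img = synthgen.gen_wedge_image(true_curve, spec, scene)
        n_wedge = int(round(spec.length / 0.01))
        h, w = img.shape
        curve = fit_wedge_calibration(img, spec, [(2.0, h / 2), (n_wedge - 3.0, h / 2)],
                                      (n_wedge + 5, 2, w - 3, h - 3),
                                      start_offset_cm=2.0 * 0.01)
        assert curve.n_points >= 500
        assert curve.slope == pytest.approx(true_curve.slope, rel=0.01)
        assert curve.fit_r2 > 0.999

    @pytest.mark.parametrize("noise_sd", [0.0, 0.5, 2.0])
    def test_slope_error_shrinks_with_sample_count(self, true_curve, noise_sd):
        # calibration-recovery invariant: error at n~1000 below error at n~50,
        # averaged over 20 seeds, at each noise level
        spec = WedgeStandard()
        errs = {False: [], True: []}
        for seed in range(20):
            scene = synthgen.SceneSpec(pixel_size=0.01, grayscale_noise_sd=noise_sd,
                                       seed=seed)
            img = synthgen.gen_wedge_image(true_curve, spec, scene)
            n_wedge = int(round(spec.length / 0.01))
            h, w = img.shape
            air = (n_wedge + 5, 2, w - 3, h - 3)
            for coarse in (False, True):
                step = 20.0 if coarse else 1.0  # ~50 vs ~1000 samples
                curve = fit_wedge_calibration(
                    img, spec, [(2.0, h / 2), (n_wedge - 3.0, h / 2)], air,
                    step_px=step, width=11, start_offset_cm=2.0 * 0.01)
                errs[coarse].append(abs(curve.slope - true_curve.slope))
        assert np.mean(errs[False]) <= np.mean(errs[True])

    def test_too_few_samples_rejected(self, true_curve):
        spec = WedgeStandard()
        scene = synthgen.SceneSpec(pixel_size=0.01, seed=0)
        img = synthgen.gen_wedge_image(true_curve, spec, scene)
        h = img.shape[0]
        with pytest.raises(ValueError, match="samples"):
            fit_wedge_calibration(img, spec, [(2.0, h / 2), (3.0, h / 2)],
                                  (980, 2, 1010, h - 3), step_px=1.0)


class TestValidateCalibration:
    def test_air_anchor_residual_zero(self):
        curve = CalibrationCurve.from_points([200.0, 50.0], [0.0, 2.71])
        report = validate_calibration(curve, 200.0, 0.0, tolerance=0.05)
        assert report.residual == pytest.approx(0.0, abs=1e-12)
        assert report.passed

    def test_aragonite_standard_tolerance(self, true_curve):
        lum = float(true_curve.luminance(2.93))
        report = validate_calibration(true_curve, lum, 2.93, tolerance=0.05)
        assert report.passed and report.predicted_density == pytest.approx(2.93)

    def test_perturbed_intercept_reported_and_failed(self):
        curve = CalibrationCurve.from_points([200.0, 50.0], [0.0, 2.71])
        shifted = CalibrationCurve(slope=curve.slope, intercept=curve.intercept + 0.1)
        report = validate_calibration(shifted, 200.0, 0.0, tolerance=0.05)
        assert report.residual == pytest.approx(0.1)
        assert not report.passed


class TestExtractTransect:
    def test_constant_image_gives_constant_profile(self, true_curve):
        img = CoreImage(np.full((100, 40), 20000.0), 16, 0.005)
        prof = extract_transect(img, [(20.0, 5.0), (20.0, 90.0)], 11, true_curve)
        assert np.allclose(prof.densities, true_curve.density(20000.0))
        assert np.all(np.diff(prof.positions) > 0)

    def test_piecewise_bands_recovered(self, true_curve, synthetic_core,
                                       center_profile):
        # oracle: direct indexing of the generating density array
        truth, scene, image, layout = synthetic_core(seed=4, noise_sd=0.0)
        prof = center_profile(image)
        edges_px = np.concatenate([[0.0], layout["end_px"].to_numpy()])
        dens = layout["true_density"].to_numpy()
        pos_px = prof.positions / scene.pixel_size
        idx = np.clip(np.searchsorted(edges_px, pos_px, side="right") - 1,
                      0, dens.size - 1)
        interior = np.ones_like(pos_px, dtype=bool)
        for e in edges_px:  # skip samples within 2 px of an edge (the
            interior &= np.abs(pos_px - e) > 2.0  # rendering anti-aliases there)
        quant = abs(true_curve.slope)
        assert np.all(np.abs(prof.densities[interior] - dens[idx][interior])
                      <= 2 * quant)

    def test_width_must_be_odd(self, true_curve):
        img = CoreImage(np.full((50, 50), 1000.0), 16, 0.005)
        with pytest.raises(ValueError, match="odd"):
            extract_transect(img, [(10.0, 5.0), (10.0, 45.0)], 4, true_curve)

    def test_transect_outside_image_rejected(self, true_curve):
        img = CoreImage(np.full((50, 50), 1000.0), 16, 0.005)
        with pytest.raises(ValueError, match="exits"):
            extract_transect(img, [(10.0, 5.0), (10.0, 80.0)], 1, true_curve)

    def test_oblique_bands_stretch_by_secant(self, true_curve):
        # a vertical transect through bands rotated by theta sees band lengths
        # inflated by 1/cos(theta); oracle = geometry on the ground truth
        from coralchron import banding

        theta = 30.0
        truth = synthgen.gen_growth_series(10, 0.45, 2.0, seed=5)
        scene = synthgen.SceneSpec(pixel_size=0.005, seed=5)
        image, layout = synthgen.gen_core_image(truth, true_curve, scene,
                                                width_px=200, rotation_deg=theta)
        h = image.shape[0]
        col = 100.0
        prof = extract_transect(image, [(col, 0.0), (col, h - 1.0)], 1, true_curve)
        bands = banding.detect_band_boundaries(prof, 0.05, 0.05)
        th = np.radians(theta)
        edges = np.concatenate([[0.0], layout["end_px"].to_numpy()])
        r_true = (edges - col * np.sin(th)) / np.cos(th) * scene.pixel_size
        # crossings outside the profile span are clamped away, not rendered
        inner = r_true[(r_true > 0.05) & (r_true < prof.positions[-1] - 0.05)]
        assert inner.size >= 15
        err_px = [np.min(np.abs(bands.boundaries - e)) / scene.pixel_size
                  for e in inner]
        assert max(err_px) < 1.0
        # band lengths along the transect equal true lengths / cos(theta)
        det_lengths = np.diff(np.sort([bands.boundaries[np.argmin(
            np.abs(bands.boundaries - e))] for e in inner]))
        true_lengths = np.diff(inner)
        assert np.allclose(det_lengths, true_lengths, atol=1.5 * scene.pixel_size)
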