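"""Spot detection, PSF fitting and unit derivation."""

from dataclasses import replace

import numpy as np
import pytest

import fishpol as fp
from fishpol.calibration import SpotCandidate, bimodality_coefficient
from conftest import SPARSE_NOISE_FREE, single_spot_image


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        img = fp.FluorescenceImage(np.full((32, 32), 10.0))
        out = fp.subtract_background(img)
        assert np.all(out.pixels == 0.0)
        assert out.background == 10.0

    def test_all_zero_image_unchanged(self):
        img = fp.FluorescenceImage(np.zeros((32, 32)))
        out = fp.subtract_background(img)
        assert np.all(out.pixels == 0.0)

    def test_scene_background_removed_exactly(self, sparse_scene):
        scene, mrna, _ = sparse_scene
        out = fp.subtract_background(mrna, scene.cell_polygon)
        assert out.background == pytest.approx(scene.params.background)
        # pixels far from every spot are exactly zero
        far = np.ones(mrna.shape, dtype=bool)
        for r, c in scene.spot_positions:
            rr, cc = np.indices(mrna.shape)
            far &= (rr - r) ** 2 + (cc - c) ** 2 > (10 * scene.params.unit_sigma) ** 2
        assert np.all(out.pixels[far] == 0.0)

    def test_mask_covering_whole_image_rejected(self):
        from shapely.geometry import box

        img = fp.FluorescenceImage(np.ones((20, 20)))
        with pytest.raises(ValueError, match="entire image"):
            fp.subtract_background(img, box(-5, -5, 25, 25))


class TestDetectPeaks:
    def test_flat_zero_image_gives_no_peaks(self):
        img = fp.FluorescenceImage(np.zeros((32, 32)))
        assert fp.detect_peaks(img) == []

    def test_single_gaussian_found_once(self):
        img = single_spot_image(20.0, 30.0, shape=(48, 64))
        peaks = fp.detect_peaks(img)
        assert len(peaks) == 1
        assert abs(peaks[0].center[0] - 20.0) <= 0.5
        assert abs(peaks[0].center[1] - 30.0) <= 0.5

    def test_two_separated_spots_found(self):
        px = fp.render_spots((48, 48), np.array([[15.0, 15.0], [15.0, 30.0]]), 100.0, 1.5)
        peaks = fp.detect_peaks(fp.FluorescenceImage(px))
        assert len(peaks) == 2

    def test_sorted_by_decreasing_peak_value(self):
        px = fp.render_spots((48, 48), np.array([[15.0, 15.0]]), 50.0, 1.5)
        fp.render_spots((48, 48), np.array([[30.0, 30.0]]), 100.0, 1.5, out=px)
        peaks = fp.detect_peaks(fp.FluorescenceImage(px))
        vals = [p.peak_value for p in peaks]
        assert vals == sorted(vals, reverse=True)

    def test_nonpositive_separation_rejected(self):
        img = fp.FluorescenceImage(np.zeros((32, 32)))
        with pytest.raises(ValueError, match="min_separation"):
            fp.detect_peaks(img, min_separation_px=0.0)

    def test_full_recovery_no_false_positives_noise_free(self, sparse_cohort):
        """All well-separated spots recovered with zero false positives."""
        found, truth = 0, 0
        for scene, mrna, _ in sparse_cohort:
            sub = fp.subtract_background(mrna, scene.cell_polygon)
            peaks = fp.detect_peaks(sub)
            truth += len(scene.spot_positions)
            assert len(peaks) == len(scene.spot_positions)  # no false positives
            for p in peaks:
                d = np.linalg.norm(scene.spot_positions - np.array(p.center), axis=1)
                assert d.min() <= 0.75
                found += 1
        assert found >= 0.95 * truth


class TestFitPsf:
    def test_exact_on_noise_free_gaussian(self):
        img = single_spot_image(24.0, 24.0, amplitude=100.0, sigma=1.5, background=5.0)
        cand = SpotCandidate(center=(24.0, 24.0), peak_value=105.0)
        fit = fp.fit_psf(img, cand)
        assert fit.accepted
        assert fit.fit_amplitude == pytest.approx(100.0, rel=1e-6)
        assert fit.fit_sigma == pytest.approx(1.5, rel=1e-6)
        assert fit.fit_background == pytest.approx(5.0, abs=1e-5)
        assert fit.fit_rss < 1e-10

    def test_subpixel_center_recovered(self):
        img = single_spot_image(24.3, 23.6)
        fit = fp.fit_psf(img, SpotCandidate(center=(24.0, 24.0), peak_value=1.0))
        assert fit.center[0] == pytest.approx(24.3, abs=1e-6)
        assert fit.center[1] == pytest.approx(23.6, abs=1e-6)

    def test_window_of_zeros_not_accepted(self):
        img = fp.FluorescenceImage(np.zeros((32, 32)))
        fit = fp.fit_psf(img, SpotCandidate(center=(16.0, 16.0), peak_value=0.0))
        assert not fit.accepted

    def test_window_off_image_rejected(self):
        img = single_spot_image(2.0, 2.0)
        with pytest.raises(ValueError, match="off the image"):
            fp.fit_psf(img, SpotCandidate(center=(2.0, 2.0), peak_value=1.0))

    def test_amplitude_recovered_under_read_noise(self):
        """Median amplitude error stays within 5% at read-noise sd 1."""
        rng = np.random.default_rng(0)
        amps = []
        for _ in range(100):
            img = single_spot_image(24.0, 24.0, amplitude=100.0, sigma=1.5)
            noisy = fp.FluorescenceImage(img.pixels + rng.normal(0, 1.0, img.shape))
            fit = fp.fit_psf(noisy, SpotCandidate(center=(24.0, 24.0), peak_value=100.0))
            if fit.accepted:
                amps.append(fit.fit_amplitude)
        assert len(amps) >= 95
        assert abs(np.median(amps) - 100.0) / 100.0 < 0.05


def _cands(amplitudes, sigmas):
    return [
        SpotCandidate(center=(0.0, 0.0), peak_value=a, fit_amplitude=a, fit_sigma=s,
                      accepted=True)
        for a, s in zip(amplitudes, sigmas)
    ]


class TestDeriveUnit:
    def test_degenerate_distribution(self):
        unit = fp.derive_unit(_cands([100.0] * 100, [1.5] * 100))
        assert unit.amplitude == 100.0
        assert unit.sigma == 1.5
        assert unit.integrated_intensity == pytest.approx(2 * np.pi * 100 * 2.25)
        assert unit.n_support == 100
        assert unit.trim_fraction_applied == 0.0

    def test_upper_mode_trimmed_from_mixture(self):
        rng = np.random.default_rng(1)
        amps = np.concatenate([rng.normal(100, 5, 90), rng.normal(300, 5, 10)])
        sigs = rng.normal(1.5, 0.05, 100)
        unit = fp.derive_unit(_cands(amps, sigs))
        assert abs(unit.amplitude - 100.0) / 100.0 < 0.05
        assert unit.trim_fraction_applied > 0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            fp.derive_unit([])

    def test_size_bounds_filter(self):
        # all candidates too wide -> no support
        with pytest.raises(ValueError, match="insufficient"):
            fp.derive_unit(_cands([100.0] * 20, [5.0] * 20))

    def test_idempotent_on_survivors(self):
        rng = np.random.default_rng(2)
        amps = np.concatenate([rng.normal(100, 5, 90), rng.normal(300, 5, 10)])
        sigs = rng.normal(1.5, 0.05, 100)
        u1, survivors = fp.derive_unit(_cands(amps, sigs), return_survivors=True)
        u2 = fp.derive_unit(survivors)
        assert u2.amplitude == pytest.approx(u1.amplitude, rel=1e-12)
        assert u2.sigma == pytest.approx(u1.sigma, rel=1e-12)
        assert u2.trim_fraction_applied == 0.0

    def test_bimodality_coefficient_flags_two_modes(self):
        rng = np.random.default_rng(3)
        bimodal = np.concatenate([rng.normal(0, 0.5, 200), rng.normal(10, 0.5, 200)])
        unimodal = rng.normal(5, 1.0, 400)
        assert bimodality_coefficient(bimodal) > 0.555
        assert bimodality_coefficient(unimodal) < 0.555


class TestCalibratePipeline:
    def test_unit_matches_generator_noise_free(self, sparse_cohort, calibrated_unit):
        p = sparse_cohort[0][0].params
        truth = 2 * np.pi * p.unit_amplitude * p.unit_sigma**2
        assert abs(calibrated_unit.integrated_intensity - truth) / truth < 0.05

    def test_unit_roundtrip_json(self, calibrated_unit):
        d = calibrated_unit.to_dict()
        back = fp.UnitModel.from_dict(d)
        assert back.amplitude == calibrated_unit.amplitude
        assert back.sigma == calibrated_unit.sigma

    def test_noisy_calibration_reasonable(self, noisy_cohort):
        unit, cands = fp.calibrate_unit(
            [m for _, m, _ in noisy_cohort],
            [s.cell_polygon for s, _, _ in noisy_cohort],
        )
        p = noisy_cohort[0][0].params
        truth = 2 * np.pi * p.unit_amplitude * p.unit_sigma**2
        # shot noise + overlap: allow 20% on the integrated intensity
        assert abs(unit.integrated_intensity - truth) / truth < 0.20
        assert unit.n_support >= 10
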