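"""Linear and reconstruction count estimators."""

from dataclasses import replace

import numpy as np
import pytest
from shapely.geometry import box

import fishpol as fp
from conftest import SPARSE_NOISE_FREE, TRUE_UNIT, single_spot_image


def _dense_params(n_spots, seed):
    """Crowded scene: small cell so spot spacing is around 2 sigma."""
    return fp.SceneParams(
        image_shape=(64, 64),
        cell_axes=(16.0, 11.0),
        cell_center=(32.0, 32.0),
        n_spots=n_spots,
        seed=seed,
        poisson_noise=False,
        read_noise_sd=0.0,
    )


class TestLinearEstimate:
    def test_single_unit_inside_roi(self):
        img = single_spot_image(24.0, 24.0, amplitude=TRUE_UNIT.amplitude,
                                sigma=TRUE_UNIT.sigma)
        n = fp.linear_estimate(img, box(4, 4, 44, 44), TRUE_UNIT)
        assert n == pytest.approx(1.0, abs=0.02)

    def test_seven_separated_units(self):
        params = replace(SPARSE_NOISE_FREE, n_spots=7, background=0.0, seed=2)
        scene, mrna, _ = fp.render_scene(params)
        rows, cols = params.image_shape
        n = fp.linear_estimate(mrna, box(0, 0, cols - 1, rows - 1), TRUE_UNIT)
        assert n == pytest.approx(7.0, abs=0.1)

    def test_background_only_roi_is_zero(self, sparse_scene):
        scene, mrna, _ = sparse_scene
        sub = fp.subtract_background(mrna, scene.cell_polygon)
        # a corner far from the cell
        assert fp.linear_estimate(sub, box(0, 0, 8, 8), TRUE_UNIT) == 0.0

    def test_nonpositive_unit_rejected(self, sparse_scene):
        _, mrna, _ = sparse_scene
        with pytest.raises(ValueError):
            fp.UnitModel(amplitude=0.0, sigma=1.5)

    def test_empty_roi_rejected(self, sparse_scene):
        _, mrna, _ = sparse_scene
        with pytest.raises(ValueError, match="no pixel centres"):
            fp.linear_estimate(mrna, box(0.1, 0.1, 0.2, 0.2), TRUE_UNIT)

    def test_whole_cell_conservation(self):
        """Noise-free, interior spots: whole-cell count equals truth within 3%."""
        params = replace(SPARSE_NOISE_FREE, seed=23)
        scene, mrna, _ = fp.render_scene(params)
        sub = fp.subtract_background(mrna, scene.cell_polygon)
        roi = scene.cell_polygon.buffer(4 * params.unit_sigma)
        n = fp.linear_estimate(sub, roi, TRUE_UNIT)
        assert abs(n - params.n_spots) / params.n_spots < 0.03

    def test_anterior_plus_posterior_equals_whole(self, sparse_scene):
        scene, mrna, _ = sparse_scene
        sub = fp.subtract_background(mrna, scene.cell_polygon)
        pair = fp.bisect_cell(
            scene.cell_polygon, scene.nucleus_centroid, scene.aggregation_point
        )
        ant, post = fp.linear_estimate_pair(sub, pair, TRUE_UNIT)
        from fishpol.geometry import roi_pair_masks

        whole = np.logical_or(*roi_pair_masks(sub.shape, pair))
        total = fp.linear_estimate(sub, whole, TRUE_UNIT)
        assert ant + post == pytest.approx(total, rel=1e-9)


class TestReconstruct:
    def test_single_unit_single_step(self):
        img = single_spot_image(24.0, 24.0, amplitude=TRUE_UNIT.amplitude,
                                sigma=TRUE_UNIT.sigma)
        trace = fp.reconstruct(img, box(4, 4, 44, 44), TRUE_UNIT, jitter_px=0.0)
        assert trace.final_count == 1
        assert np.linalg.norm(trace.placements[0] - [24.0, 24.0]) <= 1.0
        assert trace.converged

    def test_flat_zero_image_empty_trace(self):
        img = fp.FluorescenceImage(np.zeros((32, 32)))
        trace = fp.reconstruct(img, box(2, 2, 30, 30), TRUE_UNIT)
        assert trace.final_count == 0
        assert trace.converged

    def test_unit_wider_than_mask_rejected(self):
        img = fp.FluorescenceImage(np.ones((32, 32)))
        wide = fp.UnitModel(amplitude=10.0, sigma=3.0)
        with pytest.raises(ValueError, match="wider than the mask"):
            fp.reconstruct(img, box(10, 10, 14, 14), wide)

    def test_overlapping_units_counted_within_one(self):
        """Ten spots at ~2 sigma spacing: median count over seeds within +/-1."""
        px = np.zeros((48, 48))
        positions = np.array([[24.0, 8.0 + 3.0 * k] for k in range(10)])
        fp.render_spots((48, 48), positions, TRUE_UNIT.amplitude, TRUE_UNIT.sigma, out=px)
        img = fp.FluorescenceImage(px)
        counts = [
            fp.reconstruct(img, box(2, 2, 46, 46), TRUE_UNIT, seed=s).final_count
            for s in range(25)
        ]
        assert abs(np.median(counts) - 10) <= 1

    def test_ssd_strictly_decreases(self):
        params = _dense_params(20, seed=6)
        scene, mrna, _ = fp.render_scene(params)
        sub = fp.subtract_background(mrna, scene.cell_polygon)
        trace = fp.reconstruct(sub, scene.cell_polygon, TRUE_UNIT, seed=1)
        path = np.concatenate([[trace.initial_ssd], trace.ssd_after_each])
        assert np.all(np.diff(path) < 0)
        assert trace.final_count == len(trace.placements)


class TestSimulatedEstimate:
    def test_single_rep_zero_sd(self, sparse_scene):
        scene, mrna, _ = sparse_scene
        sub = fp.subtract_background(mrna, scene.cell_polygon)
        est = fp.simulated_estimate(sub, scene.cell_polygon, TRUE_UNIT, n_reps=1)
        assert est.sim_count_sd == 0.0
        assert est.n_reps == 1

    def test_agrees_with_linear_in_sparse_regime(self, sparse_scene):
        scene, mrna, _ = sparse_scene
        sub = fp.subtract_background(mrna, scene.cell_polygon)
        roi = scene.cell_polygon.buffer(4 * scene.params.unit_sigma)
        est = fp.simulated_estimate(sub, roi, TRUE_UNIT, n_reps=10, master_seed=3)
        tol = max(1.0, 0.05 * est.linear_count)
        assert abs(est.sim_count_mean - est.linear_count) <= tol

    def test_per_roi_means_near_truth(self):
        """Posterior-enriched scene: per-half means within +/-2 of truth."""
        params = replace(
            SPARSE_NOISE_FREE, n_spots=14, enrichment=0.75, seed=31,
            min_spot_separation=7.0,
        )
        scene, mrna, _ = fp.render_scene(params)
        sub = fp.subtract_background(mrna, scene.cell_polygon)
        pair = fp.bisect_cell(
            scene.cell_polygon, scene.nucleus_centroid, scene.aggregation_point
        )
        res = fp.simulated_estimate(sub, pair, TRUE_UNIT, n_reps=10, master_seed=5)
        assert abs(res["anterior"].sim_count_mean - scene.true_anterior_count) <= 2
        assert abs(res["posterior"].sim_count_mean - scene.true_posterior_count) <= 2

    def test_invalid_reps_rejected(self, sparse_scene):
        scene, mrna, _ = sparse_scene
        with pytest.raises(ValueError):
            fp.simulated_estimate(mrna, scene.cell_polygon, TRUE_UNIT, n_reps=0)


class TestAverageImage:
    def test_single_trace_single_placement(self):
        img = single_spot_image(24.0, 24.0, amplitude=TRUE_UNIT.amplitude,
                                sigma=TRUE_UNIT.sigma)
        trace = fp.reconstruct(img, box(4, 4, 44, 44), TRUE_UNIT, jitter_px=0.0)
        avg = fp.average_image([trace], img.shape, TRUE_UNIT)
        expected = fp.render_spots(img.shape, trace.placements, TRUE_UNIT.amplitude,
                                   TRUE_UNIT.sigma)
        np.testing.assert_allclose(avg.pixels, expected)

    def test_identical_traces_idempotent(self):
        img = single_spot_image(20.0, 20.0, amplitude=TRUE_UNIT.amplitude,
                                sigma=TRUE_UNIT.sigma)
        trace = fp.reconstruct(img, box(4, 4, 44, 44), TRUE_UNIT, jitter_px=0.0)
        one = fp.average_image([trace], img.shape, TRUE_UNIT)
        three = fp.average_image([trace] * 3, img.shape, TRUE_UNIT)
        np.testing.assert_allclose(one.pixels, three.pixels)

    def test_integrated_intensity_conserved(self, sparse_scene):
        scene, mrna, _ = sparse_scene
        sub = fp.subtract_background(mrna, scene.cell_polygon)
        roi = scene.cell_polygon.buffer(4 * scene.params.unit_sigma)
        est = fp.simulated_estimate(sub, roi, TRUE_UNIT, n_reps=25, master_seed=9)
        avg = fp.average_image(est.traces, sub.shape, TRUE_UNIT)
        n = avg.pixels.sum() / TRUE_UNIT.integrated_intensity
        assert abs(n - scene.params.n_spots) <= 1

    def test_shape_mismatch_rejected(self):
        img = single_spot_image(24.0, 24.0, amplitude=TRUE_UNIT.amplitude,
                                sigma=TRUE_UNIT.sigma)
        trace = fp.reconstruct(img, box(4, 4, 44, 44), TRUE_UNIT)
        with pytest.raises(ValueError, match="shape"):
            fp.average_image([trace], (64, 64), TRUE_UNIT)

    def test_no_traces_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fp.average_image([], (32, 32), TRUE_UNIT)
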