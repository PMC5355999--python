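import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from aggsplit.core import ChannelGeometry, ImageStack, PipelineConfig
from aggsplit.detection import (
    CoVMap,
    GradientMap,
    build_cov_reference,
    calibrate_threshold,
    correct_blur,
    correct_illumination,
    detect_structures,
    enhance_contrast,
    fit_illumination,
    local_gradient_magnitude,
    normalize_gradient,
    _prepare_gradient,
    _threshold_areas,
)
from aggsplit.synthetic import (
    GroundTruth,
    SceneSpec,
    _chain_radius_um,
    render_stack,
    sample_ground_truth,
)


@pytest.fixture(scope="module")
def small_reference(small_geometry):
    spec = SceneSpec(n_frames=12, structures_per_frame=30, mean_Astar=1.0,
                     rng_seed=17)
    return render_stack(sample_ground_truth(spec, small_geometry),
                        small_geometry, spec)


@pytest.fixture(scope="module")
def small_threshold(small_reference, small_config):
    t, m = calibrate_threshold(small_reference, small_config)
    return t


def _lone_structures(geometry, records):
    return GroundTruth(records=pd.DataFrame(records))


class TestEnhanceContrast:
    def test_full_range_frame_unchanged(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 1, (16, 16))
        frame.flat[0], frame.flat[1] = 0.0, 1.0
        out = enhance_contrast(frame, percentiles=(0, 100))
        assert np.allclose(out, frame)

    def test_min_max_stretch_of_three_levels(self):
        frame = np.array([[0.4, 0.5, 0.6]] * 3)
        out = enhance_contrast(frame, percentiles=(0, 100))
        assert np.allclose(np.unique(out), [0.0, 0.5, 1.0])

    def test_lower_percentile_maps_to_zero(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(0.2, 0.9, (64, 64))
        out = enhance_contrast(frame, percentiles=(5, 95))
        assert np.percentile(out, 5) == pytest.approx(0.0, abs=0.02)
        assert np.percentile(out, 95) == pytest.approx(1.0, abs=0.02)

    def test_constant_frame_warns_and_passes_through(self):
        frame = np.full((8, 8), 0.3)
        with pytest.warns(UserWarning, match="constant frame"):
            out = enhance_contrast(frame)
        assert np.array_equal(out, frame)


class TestIlluminationCorrection:
    def test_flat_frame_unchanged(self):
        frame = np.full((40, 40), 0.8)
        out = correct_illumination(frame)
        assert np.allclose(out, frame, atol=1e-6)

    def test_vignetted_flat_field_recovered(self, small_geometry):
        spec = SceneSpec(n_frames=1, structures_per_frame=0.0, rng_seed=3,
                         noise_sd=0.0, vignette_strength=0.3, hct_appearance=0.0)
        stack = render_stack(sample_ground_truth(spec, small_geometry),
                             small_geometry, spec)
        mask = small_geometry.channel_mask()
        out = correct_illumination(stack.frames[0], mask=mask)
        interior = out[mask]
        assert interior.std() / interior.mean() < 0.01

    def test_vignette_centre_recovered(self, small_geometry):
        spec = SceneSpec(n_frames=1, structures_per_frame=0.0, rng_seed=3,
                         noise_sd=0.002, vignette_strength=0.3, hct_appearance=0.0)
        stack = render_stack(sample_ground_truth(spec, small_geometry),
                             small_geometry, spec)
        popt, _ = fit_illumination(stack.frames[0])
        nr, nc = small_geometry.frame_shape_px
        assert abs(popt[1] - nr / 2) < 5 and abs(popt[2] - nc / 2) < 5


class TestLocalGradient:
    def test_constant_frame_gives_zero_map(self, small_geometry):
        g = local_gradient_magnitude(np.full((10, 10), 0.5), small_geometry)
        interior = g.values[1:-1, 1:-1]
        assert np.all(interior == 0.0)
        assert np.all(np.isnan(g.values[0, :]))

    def test_vertical_step_matches_hand_computation(self, small_geometry):
        frame = np.full((5, 5), 0.2)
        frame[:, 3:] = 0.7
        g = local_gradient_magnitude(frame, small_geometry, diag_ds_um=1.61)
        # pixel (2, 2): E-W = 0.5/1.30, N-S = 0, both diagonals = 0.5/1.61
        q_ew = 0.5 / 1.30
        q_diag = 0.5 / 1.61
        expected = math.sqrt((q_ew**2 + 0.0 + 2 * q_diag**2) / 4.0)
        assert g.values[2, 2] == pytest.approx(expected, rel=1e-12)

    def test_linear_ramp_gives_uniform_magnitude(self, small_geometry):
        col = np.linspace(0.1, 0.9, 30)
        frame = np.tile(col, (20, 1))
        g = local_gradient_magnitude(frame, small_geometry)
        interior = g.values[1:-1, 1:-1]
        assert np.allclose(interior, interior[0, 0], rtol=1e-9)


class TestNormalizeGradient:
    def test_global_scaling_cancels(self, small_geometry):
        rng = np.random.default_rng(2)
        frame = rng.uniform(0.2, 0.6, (20, 20))
        g1 = normalize_gradient(local_gradient_magnitude(frame, small_geometry), frame)
        scaled = 1.5 * frame
        g2 = normalize_gradient(local_gradient_magnitude(scaled, small_geometry), scaled)
        assert np.allclose(g1.values[1:-1, 1:-1], g2.values[1:-1, 1:-1], rtol=1e-9)

    def test_division_by_local_mean(self, small_geometry):
        frame = np.full((5, 5), 0.5)
        grad = GradientMap(values=np.full((5, 5), 0.4))
        out = normalize_gradient(grad, frame)
        assert out.values[2, 2] == pytest.approx(0.8)

    def test_near_black_region_flagged_undefined(self, small_geometry):
        frame = np.full((10, 10), 0.5)
        frame[4:7, 4:7] = 0.0
        g = normalize_gradient(local_gradient_magnitude(frame, small_geometry), frame)
        assert np.isnan(g.values[5, 5])


class TestCoVReference:
    def test_uniform_texture_maps_to_unity(self, small_geometry):
        rng = np.random.default_rng(4)
        frames = np.clip(0.7 + 0.02 * rng.standard_normal((12, 260, 420)), 0, 1)
        stack = ImageStack(frames, small_geometry)
        cov = build_cov_reference(stack)
        from scipy import ndimage
        deep = ndimage.binary_erosion(small_geometry.channel_mask(), iterations=8)
        assert cov.values.max() == 1.0
        assert np.mean(cov.values[deep] >= 0.9) > 0.9

    def test_blurred_rectangle_scores_below_surroundings(self, small_geometry):
        blur = (20, 140, 5, 110, 0.9)
        spec = SceneSpec(n_frames=16, structures_per_frame=30, mean_Astar=1.0,
                         rng_seed=19, blur_regions=[blur])
        stack = render_stack(sample_ground_truth(spec, small_geometry),
                             small_geometry, spec)
        cov = build_cov_reference(stack)
        inside = np.median(cov.values[40:120, 20:100])
        outside = np.median(cov.values[40:120, 320:400])
        assert inside < outside

    def test_constant_stack_rejected(self, small_geometry):
        stack = ImageStack(np.full((4, 260, 420), 0.5), small_geometry)
        with pytest.raises(ValueError, match="degenerate reference"):
            build_cov_reference(stack)


class TestCorrectBlur:
    def test_unaffected_map_is_identity(self):
        g = GradientMap(values=np.random.default_rng(0).uniform(0, 1, (8, 8)))
        cov = CoVMap(values=np.ones((8, 8)))
        out = correct_blur(g, cov)
        assert np.array_equal(out.values, g.values)

    def test_division_by_cov_value(self):
        g = GradientMap(values=np.full((4, 4), 0.4))
        cov = CoVMap(values=np.full((4, 4), 0.87))
        out = correct_blur(g, cov)
        assert np.allclose(out.values, 0.4 / 0.87)

    def test_blur_correction_restores_detected_areas(self, small_geometry,
                                                     small_config):
        """Identical populations in both daughters, one seen through a local
        blur: uncorrected detection disagrees strongly between the regions,
        corrected detection agrees within 10%."""
        blur = (20, 140, 5, 110, 0.9)
        ref_spec = SceneSpec(n_frames=25, structures_per_frame=30,
                             mean_Astar=1.0, rng_seed=19, blur_regions=[blur])
        reference = render_stack(sample_ground_truth(ref_spec, small_geometry),
                                 small_geometry, ref_spec)
        cov = build_cov_reference(reference)
        thr, _ = calibrate_threshold(reference, small_config)
        spec = SceneSpec(n_frames=25, structures_per_frame=30, mean_Astar=2.0,
                         rng_seed=23, blur_regions=[blur],
                         branches=("left", "right"))
        stack = render_stack(sample_ground_truth(spec, small_geometry),
                             small_geometry, spec)
        ratios = {}
        for corrected in (False, True):
            cfg = dataclasses.replace(small_config, blur_correction=corrected)
            det = detect_structures(stack, thr, cfg,
                                    cov=cov if corrected else None).records
            cols = small_geometry.to_pixel_coords(det.xstar, det.ystar)[1]
            mean_in = det[cols < 110]["area_um2"].mean()
            mean_out = det[cols > 310]["area_um2"].mean()
            ratios[corrected] = mean_in / mean_out
        assert abs(ratios[False] - 1.0) > 0.25
        assert abs(ratios[True] - 1.0) <= 0.10


class TestCalibration:
    def test_mean_area_decreases_with_threshold(self, small_reference,
                                                small_config, small_threshold):
        from scipy import ndimage
        geom = small_config.geometry
        interior = ndimage.binary_erosion(geom.channel_mask(), iterations=2)
        mask = geom.channel_mask()
        px_area = geom.um_per_px**2
        min_area = small_config.noise_fraction * small_config.Ac_um2

        def mean_area(t):
            areas = []
            for fr in small_reference:
                g = _prepare_gradient(fr, small_config, mask, None)
                _, counts, keep = _threshold_areas(g, t, interior, px_area, min_area)
                if keep.size:
                    areas.append(counts[keep - 1] * px_area)
            return np.mean(np.concatenate(areas)) if areas else 0.0

        assert mean_area(1.3 * small_threshold) < mean_area(small_threshold)

    def test_calibrated_mean_hits_characteristic_area(self, small_reference,
                                                      small_config):
        t, achieved = calibrate_threshold(small_reference, small_config)
        assert abs(achieved - small_config.Ac_um2) <= 0.02 * small_config.Ac_um2

    def test_blank_stack_fails_calibration(self, small_geometry, small_config):
        spec = SceneSpec(n_frames=4, structures_per_frame=0.0, rng_seed=0)
        blank = render_stack(sample_ground_truth(spec, small_geometry),
                             small_geometry, spec)
        with pytest.raises(ValueError, match="calibration failed"):
            calibrate_threshold(blank, small_config)


class TestDetectStructures:
    def test_blank_stack_gives_empty_table(self, small_geometry, small_config,
                                           small_threshold):
        spec = SceneSpec(n_frames=2, structures_per_frame=0.0, rng_seed=1)
        blank = render_stack(sample_ground_truth(spec, small_geometry),
                             small_geometry, spec)
        table = detect_structures(blank, small_threshold, small_config)
        assert len(table) == 0

    def test_known_structures_recovered_within_error_scale(
            self, small_geometry, small_config, small_threshold):
        # a grid of identical 45 um^2 structures; mean detected area within
        # the method's ~15% error scale
        area, n_cells = 45.0, 3
        radius = _chain_radius_um(area, n_cells)
        rows = []
        for i, xs in enumerate(np.linspace(-0.4, 0.4, 6)):
            for j, ys in enumerate((-1.05, -0.9, -0.75, -0.6)):
                rows.append({
                    "frame_index": (i + j) % 2, "n_cells": n_cells,
                    "true_area_um2": area, "true_Astar": area / 15,
                    "center_xstar": xs, "center_ystar": ys,
                    "branch": "parent", "angle_rad": math.pi / 2,
                    "radius_um": radius,
                })
        gt = _lone_structures(small_geometry, rows)
        spec = SceneSpec(n_frames=2, rng_seed=11)
        stack = render_stack(gt, small_geometry, spec)
        det = detect_structures(stack, small_threshold, small_config).records
        assert len(det) == len(rows)
        assert abs(det["area_um2"].mean() / area - 1.0) <= 0.15

    def test_noise_rule_removes_small_speck(self, small_geometry, small_config,
                                            small_threshold):
        rows = [
            {"frame_index": 0, "n_cells": 3, "true_area_um2": 45.0,
             "true_Astar": 3.0, "center_xstar": 0.1, "center_ystar": -0.8,
             "branch": "parent", "angle_rad": math.pi / 2,
             "radius_um": _chain_radius_um(45.0, 3)},
            {"frame_index": 0, "n_cells": 1, "true_area_um2": 2.0,
             "true_Astar": 2.0 / 15, "center_xstar": -0.3, "center_ystar": -0.95,
             "branch": "parent", "angle_rad": 0.0,
             "radius_um": _chain_radius_um(2.0, 1)},
        ]
        stack = render_stack(_lone_structures(small_geometry, rows),
                             small_geometry, SceneSpec(n_frames=1, rng_seed=13))
        det = detect_structures(stack, small_threshold, small_config).records
        assert len(det) == 1
        assert np.all(det["area_um2"] >= small_config.noise_fraction
                      * small_config.Ac_um2)

    def test_exposure_scaling_leaves_counts_stable(self, small_geometry,
                                                   small_config, small_threshold):
        spec = SceneSpec(n_frames=6, structures_per_frame=40, mean_Astar=2.0,
                         rng_seed=29)
        stack = render_stack(sample_ground_truth(spec, small_geometry),
                             small_geometry, spec)
        counts = []
        for c in (0.6, 0.9):  # 1.5x relative exposure range
            scaled = ImageStack(stack.frames * c, small_geometry)
            counts.append(len(detect_structures(scaled, small_threshold,
                                                small_config)))
        assert abs(counts[1] - counts[0]) <= max(0.02 * counts[0], 1)

    def test_identical_inputs_give_identical_tables(self, small_geometry,
                                                    small_config, small_threshold):
        spec = SceneSpec(n_frames=2, structures_per_frame=30, mean_Astar=2.0,
                         rng_seed=31)
        stack = render_stack(sample_ground_truth(spec, small_geometry),
                             small_geometry, spec)
        t1 = detect_structures(stack, small_threshold, small_config)
        t2 = detect_structures(stack, small_threshold, small_config)
        pd.testing.assert_frame_equal(t1.records, t2.records)
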