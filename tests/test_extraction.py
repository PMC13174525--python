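"""Fiber tracing: enhancement, binarisation, centerline/width recovery, masks."""

import numpy as np
import pytest

from _util import (
    angle_diff_deg,
    extract_all,
    match_to_truth,
    phantom_section,
    straight_planar_config,
    trace_angle_deg,
)
from rifiber.errors import ValidationError
from rifiber.extraction import (
    ExtractionParams,
    FiberTrace,
    binarize_foreground,
    build_width_weighted_mask,
    enhance_section,
    trace_fibers,
)
from rifiber.phantom import generate_phantom
from rifiber.tomo import Section2D


def make_section(values, medium_ri=1.337, pixel=0.2, dz=0.4):
    return Section2D(
        values=np.asarray(values, np.float32),
        pixel_size=(pixel, pixel),
        slice_thickness=dz,
        z_index=0,
        medium_ri=medium_ri,
    )


class TestEnhance:
    def test_constant_section_stays_constant(self):
        sec = make_section(np.full((64, 64), 1.345))
        out = enhance_section(sec)
        assert np.ptp(out.values) == 0
        assert out.medium_ri == sec.medium_ri
        assert out.shape == sec.shape

    def test_zero_smoothing_is_flattening_only(self):
        # a compact bright blob on a flat background survives flattening intact
        vals = np.full((64, 64), 1.337, np.float32)
        vals[30:34, 30:34] = 1.35
        sec = make_section(vals)
        out = enhance_section(sec, ExtractionParams(smoothing_sigma_px=0))
        np.testing.assert_allclose(out.values, vals, atol=1e-6)

    def test_noise_is_reduced_against_clean_reference(self):
        clean_sec, _, _ = phantom_section(straight_planar_config(seed=2))
        noisy_sec, _, _ = phantom_section(straight_planar_config(seed=2, noise_sd=0.005))
        out = enhance_section(noisy_sec)
        resid = out.values.astype(float) - clean_sec.values.astype(float)
        assert resid.std() < 0.005


class TestBinarize:
    def test_pure_medium_gives_empty_mask(self):
        sec = make_section(np.full((32, 32), 1.337))
        assert not binarize_foreground(sec).any()

    def test_threshold_above_signal_gives_empty_mask(self):
        sec, _, _ = phantom_section(straight_planar_config(seed=0))
        mask = binarize_foreground(sec, ExtractionParams(threshold_mode=0.5))
        assert not mask.any()

    def test_recall_against_true_footprint_at_high_snr(self):
        # contrast >= 10x noise sd: recover >= 90% of the true tube footprint
        cfg = straight_planar_config(
            seed=1, noise_sd=0.002, ri_contrast_range=(0.02, 0.03)
        )
        tomo, truth = generate_phantom(cfg)
        clean_cfg = straight_planar_config(
            seed=1, noise_sd=0.0, ri_contrast_range=(0.02, 0.03)
        )
        clean, _ = generate_phantom(clean_cfg)
        z = clean.delta_n().sum(axis=(1, 2)).argmax()
        footprint = clean.values[z] > clean.medium_ri + 1e-6
        from rifiber.tomo import extract_axial_section

        sec = extract_axial_section(tomo, int(z))
        mask = binarize_foreground(enhance_section(sec), ExtractionParams())
        recall = (mask & footprint).sum() / footprint.sum()
        assert recall >= 0.9


class TestTraceFibers:
    def test_blank_section_gives_no_traces(self):
        sec = make_section(np.full((64, 64), 1.337))
        assert trace_fibers(sec, np.zeros((64, 64), bool)) == []

    def test_three_separated_fibers_recovered_with_subpixel_centerlines(self):
        sec, truth, _ = phantom_section(straight_planar_config(seed=4, n_fibers=3))
        traces, _ = extract_all(sec)
        assert len(traces) == 3
        for trace, fiber in match_to_truth(traces, truth, 0.2):
            gt_px = fiber.control_points[:, 1:] / 0.2
            devs = [
                np.min(np.linalg.norm(gt_px - p[None, :], axis=1))
                for p in trace.centerline
            ]
            assert np.mean(devs) <= 1.0

    def test_short_fiber_is_pruned(self):
        vals = np.full((64, 64), 1.337, np.float32)
        vals[30:33, 28:36] = 1.36  # ~8 px long, below the 15 px minimum
        sec = make_section(vals)
        traces, _ = extract_all(sec)
        assert traces == []

    @pytest.mark.parametrize("seed", range(8))
    def test_count_recovery_over_seeds(self, seed):
        sec, truth, _ = phantom_section(straight_planar_config(seed=seed))
        traces, _ = extract_all(sec)
        assert len(traces) == len(truth.fibers)

    @pytest.mark.parametrize("diameter_px", [3, 6, 10, 15])
    def test_width_recovery_within_one_pixel(self, diameter_px):
        cfg = straight_planar_config(
            seed=diameter_px,
            n_fibers=1,
            width_lognormal=(diameter_px * 0.2, 0.0),
        )
        sec, truth, _ = phantom_section(cfg)
        traces, _ = extract_all(sec)
        assert len(traces) == 1
        recovered = float(np.median(traces[0].widths_px))
        assert abs(recovered - diameter_px) <= 1.0

    def test_rotation_equivariance(self):
        sec, truth, _ = phantom_section(straight_planar_config(seed=6))
        traces, _ = extract_all(sec)
        rot = Section2D(
            values=np.ascontiguousarray(np.rot90(sec.values)),
            pixel_size=sec.pixel_size,
            slice_thickness=sec.slice_thickness,
            z_index=sec.z_index,
            medium_ri=sec.medium_ri,
        )
        traces_rot, _ = extract_all(rot)
        assert len(traces_rot) == len(traces)
        angles = sorted(trace_angle_deg(t) for t in traces)
        angles_rot = sorted((trace_angle_deg(t) + 90.0) % 180.0 for t in traces_rot)
        for a, b in zip(angles, angles_rot):
            assert angle_diff_deg(a, b) <= 2.0

    def test_pruning_is_monotone_in_min_length(self):
        sec, _, _ = phantom_section(straight_planar_config(seed=7))
        counts = []
        for min_len in (5.0, 15.0, 40.0, 80.0):
            traces, _ = extract_all(sec, ExtractionParams(min_fiber_length_px=min_len))
            counts.append(len(traces))
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestWidthWeightedMask:
    def test_straight_trace_pixel_count_matches_rectangle(self):
        L, w = 80.0, 5.0
        y0, x0 = 32.3, 10.0
        pts = np.stack([np.full(21, y0), np.linspace(x0, x0 + L, 21)], axis=1)
        trace = FiberTrace(fiber_id=1, centerline=pts, widths_px=np.full(21, w))
        mask = build_width_weighted_mask([trace], (128, 128))
        # independent capsule oracle: pixel centers within w/2 of the segment
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        tt = np.clip((xx - x0) / L, 0, 1)
        d2 = (yy - y0) ** 2 + (xx - (x0 + tt * L)) ** 2
        oracle = int((d2 <= (w / 2) ** 2).sum())
        assert mask.count(1) == oracle
        assert mask.count(1) == pytest.approx(L * w, rel=0.10)

    def test_disjoint_traces_get_disjoint_labels(self):
        t1 = FiberTrace(
            1, np.stack([np.full(11, 10.0), np.linspace(5, 45, 11)], axis=1), np.full(11, 4.0)
        )
        t2 = FiberTrace(
            2, np.stack([np.full(11, 40.0), np.linspace(5, 45, 11)], axis=1), np.full(11, 4.0)
        )
        mask = build_width_weighted_mask([t1, t2], (64, 64))
        assert set(np.unique(mask.label_image)) == {0, 1, 2}
        assert mask.count(1) > 0 and mask.count(2) > 0

    def test_crossing_traces_conserve_pixels(self):
        t1 = FiberTrace(
            1, np.stack([np.linspace(5, 55, 26), np.linspace(5, 55, 26)], axis=1), np.full(26, 5.0)
        )
        t2 = FiberTrace(
            2, np.stack([np.linspace(55, 5, 26), np.linspace(5, 55, 26)], axis=1), np.full(26, 5.0)
        )
        mask = build_width_weighted_mask([t1, t2], (64, 64))
        total = (mask.label_image > 0).sum()
        assert mask.count(1) + mask.count(2) == total  # no double counting

    def test_trace_outside_shape_rejected(self):
        t = FiberTrace(1, np.array([[10.0, 60.0], [10.0, 70.0]]), np.array([3.0, 3.0]))
        with pytest.raises(ValidationError):
            build_width_weighted_mask([t], (64, 64))


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            ExtractionParams(max_turn_deg=120)
        with pytest.raises(ValidationError):
            ExtractionParams(step_px=0)
        with pytest.raises(ValidationError):
            ExtractionParams(threshold_mode="magic")
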