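"""Centerline extraction, 3-D skeleton length, motility and occupancy."""

import numpy as np
import pytest

from phagoquant import (
    BorderParams,
    GapError,
    ProcessSelection,
    ProcessSkeleton,
    UndefinedMetricError,
    ValidationError,
    ZStackSeries,
    center_point,
    detect_borders,
    extract_skeleton,
    measure_process,
    motility_trace,
    occupancy_fraction,
    reorient_process,
    skeleton_length,
)
from phagoquant.synthetic import generate_process_stack

NO_SMOOTH = BorderParams(smooth_sigma=0.0, use_inflexion=False)


class TestDetectBorders:
    def test_flat_profile_is_absent(self):
        assert detect_borders(np.full(11, 5.0), background=5.0) is None

    def test_symmetric_triangle_centered(self):
        prof = np.array([0, 1, 2, 3, 2, 1, 0], dtype=float)
        xl, xr = detect_borders(prof, background=0.0, params=NO_SMOOTH)
        assert (xl + xr) / 2 == pytest.approx(3.0)

    def test_gaussian_center_recovered_subpixel(self):
        x = np.arange(41, dtype=float)
        mu, sigma = 19.3, 3.0
        prof = 100 * np.exp(-((x - mu) ** 2) / (2 * sigma**2))
        xl, xr = detect_borders(prof, background=0.0)
        assert (xl + xr) / 2 == pytest.approx(mu, abs=0.1)

    def test_half_max_width_of_gaussian(self):
        x = np.arange(61, dtype=float)
        mu, sigma = 30.0, 4.0
        prof = 50 * np.exp(-((x - mu) ** 2) / (2 * sigma**2))
        xl, xr = detect_borders(
            prof, background=0.0, params=BorderParams(smooth_sigma=0.0, use_inflexion=False)
        )
        fwhm = 2 * sigma * np.sqrt(2 * np.log(2))
        assert xr - xl == pytest.approx(fwhm, rel=0.02)

    def test_peak_touching_profile_edge_rejected(self):
        prof = np.array([9.0, 5.0, 1.0, 0.5, 0.2])
        assert detect_borders(prof, background=0.0, params=NO_SMOOTH) is None

    def test_nonfinite_profile_rejected(self):
        with pytest.raises(ValidationError):
            detect_borders(np.array([0.0, np.nan, 1.0]), 0.0)


class TestCenterPoint:
    def test_integer_central_slice(self):
        borders = {2: (1.0, 3.0), 3: (4.0, 8.0), 4: (2.0, 4.0)}
        xc, zc = center_point(borders)
        assert zc == 3
        assert xc == pytest.approx(6.0)  # only slice 3's borders used

    def test_virtual_slice_averages_flanking_borders(self):
        borders = {2: (6.0, 10.0), 3: (8.0, 12.0)}
        xc, zc = center_point(borders)
        assert zc == pytest.approx(2.5)
        assert xc == pytest.approx(9.0)  # xL=(6+8)/2=7, xR=(10+12)/2=11

    def test_single_slice_process(self):
        xc, zc = center_point({5: (2.0, 4.0)})
        assert (xc, zc) == (3.0, 5.0)

    def test_missing_central_slice_is_a_gap(self):
        with pytest.raises(GapError):
            center_point({2: (1.0, 2.0), 4: (1.0, 2.0)})  # zC=3 absent


class TestSkeletonLength:
    def test_straight_segment(self):
        sk = ProcessSkeleton(
            y=np.arange(11), xc=np.full(11, 4.0), zc=np.full(11, 2.0)
        )
        assert skeleton_length(sk, (1.0, 1.0, 1.0)) == pytest.approx(10.0)

    def test_three_four_five(self):
        sk = ProcessSkeleton(
            y=np.array([0, 1]), xc=np.array([0.0, 0.75]), zc=np.array([0.0, 0.0])
        )
        assert skeleton_length(sk, (1.0, 1.0, 1.0)) == pytest.approx(1.25)

    def test_anisotropic_voxels_converted_before_summing(self):
        sk = ProcessSkeleton(
            y=np.array([0, 1]), xc=np.array([0.0, 3.0]), zc=np.array([0.0, 1.0])
        )
        # 0.1 um lines, 0.1 um pixels, 1 um slices
        expected = np.sqrt(0.1**2 + 0.3**2 + 1.0**2)
        assert skeleton_length(sk, (0.1, 0.1, 1.0)) == pytest.approx(expected)

    def test_translation_invariance(self):
        y = np.arange(5)
        xc = np.array([0.0, 1.0, 0.5, 2.0, 1.0])
        zc = np.zeros(5)
        a = skeleton_length(ProcessSkeleton(y, xc, zc), (0.1, 0.1, 1.0))
        b = skeleton_length(ProcessSkeleton(y + 7, xc + 30, zc + 3), (0.1, 0.1, 1.0))
        assert a == pytest.approx(b)

    def test_too_few_points(self):
        with pytest.raises(UndefinedMetricError):
            skeleton_length(
                ProcessSkeleton(np.array([0]), np.array([0.0]), np.array([0.0]))
            )

    def test_matches_naive_per_pair_loop(self, rng):
        y = np.sort(rng.choice(100, size=20, replace=False))
        xc = rng.normal(size=20)
        zc = rng.normal(size=20)
        vox = (0.1, 0.1, 1.0)
        naive = sum(
            np.sqrt(
                ((y[i + 1] - y[i]) * vox[1]) ** 2
                + ((xc[i + 1] - xc[i]) * vox[0]) ** 2
                + ((zc[i + 1] - zc[i]) * vox[2]) ** 2
            )
            for i in range(19)
        )
        assert skeleton_length(ProcessSkeleton(y, xc, zc), vox) == pytest.approx(naive)


class TestMotilityTrace:
    def test_hand_case(self):
        t = motility_trace([10.0, 13.0, 7.0], frame_interval_min=1.5)
        assert list(t.motilities_um_min) == pytest.approx([2.0, 4.0])
        assert t.mean_motility == pytest.approx(3.0)
        assert t.mean_protraction == pytest.approx(2.0)
        assert t.mean_retraction == pytest.approx(4.0)

    def test_static_process_has_undefined_protraction(self):
        t = motility_trace([5.0, 5.0, 5.0], 1.5)
        assert t.mean_motility == 0.0
        assert np.isnan(t.mean_protraction) and np.isnan(t.mean_retraction)

    def test_time_reversal_swaps_protraction_and_retraction(self, rng):
        lengths = list(10 + rng.normal(size=8))
        fwd = motility_trace(lengths, 1.5)
        rev = motility_trace(lengths[::-1], 1.5)
        assert fwd.mean_motility == pytest.approx(rev.mean_motility)
        assert fwd.mean_protraction == pytest.approx(rev.mean_retraction)

    def test_triangle_inequality_on_increments(self, rng):
        lengths = 10 + rng.normal(size=10)
        t = motility_trace(lengths, 1.5)
        bound = abs(lengths[-1] - lengths[0]) / (len(lengths) - 1) / 1.5
        assert t.mean_motility >= bound - 1e-12

    def test_nonconsecutive_frames_break_pairs(self):
        t = motility_trace([10.0, 12.0, 20.0], 1.5, frame_indices=[0, 1, 5])
        assert t.pair_frames == (0,)
        assert list(t.motilities_um_min) == pytest.approx([2.0 / 1.5])

    def test_single_frame_undefined(self):
        with pytest.raises(UndefinedMetricError):
            motility_trace([10.0], 1.5)


class TestReorient:
    def test_identity_rotation_is_a_crop(self):
        data = np.arange(2 * 3 * 8 * 9, dtype=float).reshape(2, 3, 8, 9)
        stack = ZStackSeries(data, (0.1, 0.1, 1.0), 1.5)
        out = reorient_process(stack, ProcessSelection(roi=(1, 5, 2, 7)))
        assert np.array_equal(out.data, data[:, :, 1:5, 2:7])

    def test_rotation_round_trip(self):
        stack, _ = generate_process_stack(
            3, lengths_um=(8.0,), amplitude_um=0.0, peak_intensity=100.0
        )
        rot = reorient_process(stack, ProcessSelection(angle_deg=17.0))
        back = reorient_process(rot, ProcessSelection(angle_deg=-17.0))
        # compare central crops (rotation pads with zeros at corners)
        a = stack.data[0, 5]
        ny, nx = a.shape
        b = back.data[0, 5]
        cy, cx = (b.shape[0] - ny) // 2, (b.shape[1] - nx) // 2
        b = b[cy : cy + ny, cx : cx + nx]
        assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.98

    def test_90_degree_rotation_preserves_intensity(self):
        stack, _ = generate_process_stack(4, lengths_um=(10.0,), amplitude_um=0.0)
        # make an x-aligned tube by transposing the spatial axes
        xal = ZStackSeries(
            np.ascontiguousarray(np.swapaxes(stack.data, 2, 3)),
            stack.voxel_size_um,
            stack.frame_interval_min,
        )
        rot = reorient_process(xal, ProcessSelection(angle_deg=90.0))
        assert rot.data.sum() == pytest.approx(stack.data.sum(), rel=0.01)
        # and the rotated tube is measurable as y-aligned
        sk = extract_skeleton(rot.data[0], 0.0)
        assert sk.y.size > 80

    def test_invalid_roi(self):
        stack = ZStackSeries(np.zeros((1, 2, 4, 4)))
        with pytest.raises(ValidationError):
            reorient_process(stack, ProcessSelection(roi=(0, 9, 0, 2)))


class TestMeasureProcess:
    def test_noiseless_phantom_length_recovery(self):
        stack, truth = generate_process_stack(
            1, lengths_um=(30.0,) * 2, amplitude_um=1.5, wavelength_um=12.0
        )
        trace = measure_process(stack, ProcessSelection(background=0.0))
        for meas, true in zip(trace.lengths_um, truth.lengths_um):
            assert meas == pytest.approx(true, rel=0.02)

    def test_elongating_phantom_motility(self):
        lengths = tuple(15.0 + 3.0 * f for f in range(6))
        stack, truth = generate_process_stack(2, lengths_um=lengths, amplitude_um=0.0)
        trace = measure_process(stack, ProcessSelection(background=0.0))
        assert trace.mean_motility == pytest.approx(3.0 / 1.5, rel=0.10)
        assert np.isnan(trace.mean_retraction)

    def test_noise_perturbs_lengths_under_five_percent(self):
        clean, truth = generate_process_stack(
            5, lengths_um=(30.0,) * 3, amplitude_um=1.5, wavelength_um=12.0
        )
        noisy, _ = generate_process_stack(
            5, lengths_um=(30.0,) * 3, amplitude_um=1.5, wavelength_um=12.0, snr=5.0
        )
        t_clean = measure_process(clean, ProcessSelection(background=0.0))
        t_noisy = measure_process(noisy, ProcessSelection())
        for a, b in zip(t_clean.lengths_um, t_noisy.lengths_um):
            assert abs(b - a) / a < 0.05

    def test_z_drift_appears_in_recovered_centerline(self):
        """A centerline drifting in z is tracked (coarsely, via zU/zB)."""
        stack, _ = generate_process_stack(
            6,
            lengths_um=(30.0,),
            amplitude_um=0.0,
            z_amplitude_um=1.5,
            wavelength_um=30.0,
            sigma_z_um=1.2,
        )
        sk = extract_skeleton(stack.data[0], 0.0)
        assert np.ptp(sk.zc) > 0.5  # z variation detected, not flattened

    def test_lost_process_frames_are_dropped_and_reported(self):
        stack, _ = generate_process_stack(7, lengths_um=(20.0,) * 4, amplitude_um=0.0)
        data = stack.data.copy()
        data[1] = 0.0  # process vanishes in frame 1
        stack2 = ZStackSeries(data, stack.voxel_size_um, stack.frame_interval_min)
        trace = measure_process(stack2, ProcessSelection(background=0.0))
        assert trace.dropped_frames == (1,)
        # both pairs touching frame 1 are gone; only (2, 3) survives
        assert trace.pair_frames == (2,)

    def test_undetectable_everywhere_is_an_error(self):
        stack = ZStackSeries(np.zeros((3, 4, 20, 20)))
        with pytest.raises(UndefinedMetricError):
            measure_process(stack, ProcessSelection(background=0.0))


class TestOccupancy:
    def test_all_zero_image(self):
        assert occupancy_fraction(np.zeros((3, 8, 8)), threshold=0.5) == 0.0

    def test_half_filled_mask(self):
        img = np.zeros((4, 10, 10))
        img[:, :5, :] = 1.0
        assert occupancy_fraction(img, threshold=0.5) == pytest.approx(50.0)

    def test_matches_brute_force_pixel_count(self, rng):
        vol = rng.random((12, 30, 30))
        thr = 0.6
        expected = (vol > thr).sum() / vol.size * 100
        assert occupancy_fraction(vol, threshold=thr) == pytest.approx(expected)

    def test_monotone_in_threshold(self, rng):
        vol = rng.random((5, 20, 20))
        fracs = [occupancy_fraction(vol, thr) for thr in np.linspace(0.1, 0.9, 9)]
        assert np.all(np.diff(fracs) <= 0)

    def test_minimum_slice_rule_enforced(self):
        with pytest.raises(ValidationError):
            occupancy_fraction(np.ones((4, 5, 5)), threshold=0.5, min_slices=10)

    def test_otsu_auto_threshold_on_bimodal_volume(self, rng):
        vol = np.where(rng.random((10, 40, 40)) < 0.3, 10.0, 0.0)
        vol += rng.normal(0, 0.1, vol.shape)
        expected = (vol > 5).sum() / vol.size * 100
        assert occupancy_fraction(vol) == pytest.approx(expected, abs=0.5)
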