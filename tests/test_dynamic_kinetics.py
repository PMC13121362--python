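import numpy as np
import pytest

import fetquant
from fetquant.synthetic_data import base_curve
from hypothesis import given, settings, strategies as st

from fetquant import (
    DEFAULT_SCHEDULE,
    DynamicSeries,
    DynamicSpec,
    KineticConfig,
    Mask,
    PhantomSpec,
    TimeActivityCurve,
    VolumeGrid,
    classify_tac,
    classify_tumour_kinetics,
    extract_slice_tacs,
    extract_tac,
    isocontour_roi,
    make_dynamic_phantom,
    make_tac,
    summation_image,
    time_to_peak,
    ttp_min,
)

MID = DEFAULT_SCHEDULE.mid_times


def curve(values, mid=MID, **kw):
    return TimeActivityCurve(mid[: len(values)], np.asarray(values, float), **kw)


def slice_curve(values, z):
    return TimeActivityCurve(MID, np.asarray(values, float),
                             roi_scope="single-slice", slice_index=z)


class TestIsocontour:
    def test_threshold_is_fraction_of_max(self, unit_grid):
        vals = np.ones((6, 6, 6))
        vals[2, 2, 2] = 4.0
        vals[2, 2, 3] = 3.7
        vals[2, 2, 4] = 3.5
        roi = isocontour_roi(unit_grid(vals), 0.9)
        assert roi.values[2, 2, 2] == 1 and roi.values[2, 2, 3] == 1
        assert roi.values[2, 2, 4] == 0

    def test_constant_image_selects_entire_region(self, unit_grid):
        vol = unit_grid(np.full((5, 5, 5), 2.0))
        region = np.zeros((5, 5, 5))
        region[1:4, 1:4, 1:4] = 1
        roi = isocontour_roi(vol, 0.9, unit_grid(region, kind="mask"))
        np.testing.assert_array_equal(roi.values, region.astype(np.uint8))

    def test_gaussian_lesion_matches_bruteforce(self, unit_grid, rng):
        idx = np.indices((16, 16, 8)).astype(float)
        vals = 1.0 + 4.0 * np.exp(
            -((idx[0] - 8) ** 2 + (idx[1] - 8) ** 2 + (idx[2] - 4) ** 2) / 10.0
        )
        vol = unit_grid(vals)
        roi = isocontour_roi(vol, 0.9)
        oracle = (vals >= 0.9 * vals.max()).astype(np.uint8)
        np.testing.assert_array_equal(roi.values, oracle)

    def test_all_zero_image_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="all-zero"):
            isocontour_roi(unit_grid(np.zeros((4, 4, 4))), 0.9)


class TestTacExtraction:
    def _series(self, rng, shape=(8, 8, 6)):
        data = rng.uniform(0.5, 3.0, shape + (6,))
        return DynamicSeries(data, np.diag([2.0, 2.0, 2.0, 1.0]), DEFAULT_SCHEDULE)

    def test_single_voxel_roi_equals_voxel_curve(self, unit_grid, rng):
        series = self._series(rng)
        roi_vals = np.zeros((8, 8, 6))
        roi_vals[3, 4, 2] = 1
        tac = extract_tac(series, unit_grid(roi_vals, kind="mask"))
        np.testing.assert_allclose(tac.values, series.data[3, 4, 2, :])
        np.testing.assert_allclose(tac.mid_times, MID)

    def test_constant_series_gives_constant_curve(self, unit_grid):
        data = np.full((6, 6, 4, 6), 1.7)
        series = DynamicSeries(data, np.diag([2.0, 2.0, 2.0, 1.0]), DEFAULT_SCHEDULE)
        roi = np.ones((6, 6, 4))
        tac = extract_tac(series, unit_grid(roi, kind="mask"))
        np.testing.assert_allclose(tac.values, 1.7)

    def test_noiseless_generator_curve_recovered_exactly(self):
        spec = PhantomSpec(background_sd=0.0)
        dyn = DynamicSpec(schedule=DEFAULT_SCHEDULE, curve_family="decreasing",
                          peak_time_min=12.5)
        series, _, _ = make_dynamic_phantom(spec, dyn)
        _, lesion, _ = fetquant.make_static_phantom(spec)
        tac = extract_tac(series, lesion)
        expected = 2.5 * base_curve(dyn)[0]
        np.testing.assert_allclose(tac.values, expected, rtol=1e-12)

    def test_slice_curves_weighted_mean_identity(self, unit_grid, rng):
        series = self._series(rng)
        roi_vals = (rng.uniform(0, 1, (8, 8, 6)) > 0.4).astype(np.uint8)
        roi = unit_grid(roi_vals, kind="mask")
        whole = extract_tac(series, roi)
        slices = extract_slice_tacs(series, roi, min_slice_voxels=1)
        counts = [roi_vals[:, :, c.slice_index].sum() for c in slices]
        recon = sum(n * c.values for n, c in zip(counts, slices)) / sum(counts)
        np.testing.assert_allclose(recon, whole.values, rtol=1e-12)

    def test_small_slices_skipped(self, unit_grid, rng):
        series = self._series(rng)
        roi_vals = np.zeros((8, 8, 6))
        roi_vals[2:6, 2:6, 1] = 1  # 16 voxels
        roi_vals[3, 3, 2] = roi_vals[3, 4, 2] = 1  # 2 voxels < 3
        slices = extract_slice_tacs(series, unit_grid(roi_vals, kind="mask"))
        assert [c.slice_index for c in slices] == [1]

    def test_empty_roi_rejected(self, unit_grid, rng):
        series = self._series(rng)
        with pytest.raises(ValueError, match="empty"):
            extract_tac(series, unit_grid(np.zeros((8, 8, 6)), kind="mask"))


class TestClassifyTac:
    def test_monotone_rise_is_increasing(self):
        cls, ev = classify_tac(curve([1, 2, 3, 4, 5, 6]))
        assert cls == "increasing" and ev["rule"] == "continuous-rise"

    def test_rise_then_plateau_is_increasing(self):
        cls, ev = classify_tac(curve([0.5, 0.8, 1.0, 0.98, 0.97, 0.96]))
        assert cls == "increasing" and ev["rule"] == "rise-then-plateau"

    def test_peak_then_steady_fall_is_decreasing(self):
        # peak at 12.5 min then constant decline to 75% of peak
        cls, ev = classify_tac(curve([0.6, 0.9, 1.0, 0.95, 0.87, 0.75]))
        assert cls == "decreasing"
        assert ev["relative_late_change"] == pytest.approx(-0.25)

    def test_flat_with_small_jitter_is_stable(self):
        cls, ev = classify_tac(curve([1.0, 0.98, 1.01, 0.97, 0.99, 0.96]))
        assert cls == "stable"

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="4 frames"):
            classify_tac(curve([1, 2, 3]))

    @settings(max_examples=60, derandomize=True)
    @given(
        values=st.lists(st.floats(0.1, 10.0), min_size=6, max_size=6),
        scale=st.floats(0.01, 100.0),
    )
    def test_classification_is_scale_invariant(self, values, scale):
        c = curve(values)
        assert classify_tac(c)[0] == classify_tac(c.scaled(scale))[0]


class TestTimeToPeak:
    def test_monotone_curve_peaks_at_last_mid_time(self):
        assert time_to_peak(curve([1, 2, 3, 4, 5, 6])) == 35.0

    def test_earliest_max_tie_rule(self):
        c = curve([1, 5, 5, 2], mid=np.array([2.5, 7.5, 12.5, 17.5]))
        assert time_to_peak(c) == 7.5

    @pytest.mark.parametrize("family,expected_ttp", [
        ("increasing", 35.0),
        ("stable", 2.5),
        ("decreasing", 12.5),
    ])
    def test_generator_peak_recovered_noiselessly(self, family, expected_ttp):
        spec = DynamicSpec(schedule=DEFAULT_SCHEDULE, curve_family=family)
        vals, _, true_ttp = make_tac(spec)
        assert true_ttp == expected_ttp
        assert time_to_peak(curve(vals)) == expected_ttp

    def test_ttp_never_exceeds_final_mid_time(self, rng):
        for _ in range(50):
            vals = rng.uniform(0.1, 5, 6)
            assert time_to_peak(curve(vals)) <= MID[-1]


class TestTtpMin:
    def _slices(self, ttp_values):
        out = []
        for z, t in enumerate(ttp_values):
            vals = np.ones(6)
            peak_idx = int(np.argmin(np.abs(MID - t)))
            vals[peak_idx] = 2.0
            out.append(slice_curve(vals, z))
        return out

    def test_shortest_ttp_in_two_consecutive_slices(self):
        ttps, tmin, fallback = ttp_min(self._slices([35, 35, 25, 25, 12.5]))
        assert ttps == [35, 35, 25, 25, 12.5]
        assert tmin == 25.0 and not fallback

    def test_uniform_slices(self):
        _, tmin, fallback = ttp_min(self._slices([35, 35, 35]))
        assert tmin == 35.0 and not fallback

    def test_no_adjacent_repeat_falls_back_to_whole_roi(self):
        whole = curve([1, 2, 3, 4, 5, 6])  # TTP 35
        ttps, tmin, fallback = ttp_min(self._slices([35, 25, 12.5]), whole_roi_curve=whole)
        assert fallback and tmin == 35.0

    def test_gap_in_slice_indices_breaks_adjacency(self):
        slices = [slice_curve([1, 1, 1, 1, 1, 2], 0),  # TTP 35, z=0
                  slice_curve([1, 1, 1, 1, 1, 2], 2)]  # TTP 35, z=2 (not adjacent)
        whole = curve([1, 1, 2, 1, 1, 1])  # TTP 12.5
        _, tmin, fallback = ttp_min(slices, whole_roi_curve=whole)
        assert fallback and tmin == 12.5


class TestTumourLevelClass:
    def test_two_adjacent_decreasing_slices_dominate(self):
        dec = [0.6, 0.9, 1.0, 0.95, 0.87, 0.75]
        inc = [1, 2, 3, 4, 5, 6]
        slices = [slice_curve(dec, 0), slice_curve(dec, 1), slice_curve(inc, 2)]
        res = classify_tumour_kinetics(slices, curve(inc))
        assert res.curve_class == "decreasing"
        assert res.evidence["whole_roi_class"] == "increasing"

    def test_homogeneous_increasing(self):
        inc = [1, 2, 3, 4, 5, 6]
        slices = [slice_curve(inc, z) for z in range(3)]
        res = classify_tumour_kinetics(slices, curve(inc))
        assert res.curve_class == "increasing"
        assert not res.ttp_min_fallback and res.ttp_min == 35.0

    def test_non_adjacent_decreasing_slices_do_not_dominate(self):
        dec = [0.6, 0.9, 1.0, 0.95, 0.87, 0.75]
        stab = [1.0, 0.98, 1.01, 0.97, 0.99, 0.96]
        slices = [slice_curve(dec, 0), slice_curve(stab, 1), slice_curve(dec, 2)]
        res = classify_tumour_kinetics(slices, curve(stab))
        assert res.curve_class == "stable"


class TestPhantomRoundTrip:
    @pytest.mark.parametrize("family", ["increasing", "stable", "decreasing"])
    def test_noiseless_phantom_class_and_ttp_recovered(self, family):
        spec = PhantomSpec(grid_shape=(32, 32, 16), background_sd=0.0,
                           lesions=(fetquant.LesionSpec((20, 16, 8), (10.0, 8.0, 8.0), tbr=2.5),))
        dyn = DynamicSpec(schedule=DEFAULT_SCHEDULE, curve_family=family)
        series, true_cls, true_ttp = make_dynamic_phantom(spec, dyn)
        summ = summation_image(series, 10, 30)
        roi = isocontour_roi(summ, 0.9)
        whole = extract_tac(series, roi)
        slices = extract_slice_tacs(series, roi)
        res = classify_tumour_kinetics(slices, whole)
        assert res.curve_class == true_cls
        assert res.ttp_min == true_ttp
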