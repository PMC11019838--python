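"""The ROI detection chain: clot handling, filtering, anomaly scoring,
peak extraction, height equalization, FWHM and the width gate."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deeppeak.roi_detect import (
    DetectionParams,
    RoiEvent,
    bandpass_filter,
    characterize_rois,
    correct_clot,
    cumulative_scatter,
    detect_clot,
    detect_gfp_rois,
    detect_segment,
    equalize_heights,
    find_rois,
    hotelling_t2_trace,
    measure_fwhm,
    normalize_segment,
    width_gate,
)
from deeppeak.simulate import SimConfig, SizeCategory, simulate_day
from deeppeak.trace_io import SchemaError, TraceSegment

from conftest import make_segment


def _roi(start, peak, end, fwhm, seg=0):
    return RoiEvent(segment_id=seg, start_index=start, peak_index=peak,
                    end_index=end, fwhm_samples=fwhm, peak_intensity=1.0)


class TestCumulativeScatter:
    def test_zero_channels_sum_to_zero(self):
        seg = make_segment(n=100, stds=(0, 0, 0))
        for c in ("scatter405", "scatter488", "scatter633"):
            seg.channels[c][:] = 0.0
        assert np.all(cumulative_scatter(seg) == 0)

    def test_independent_baselines_sum_to_1_132_variance(self):
        seg = make_segment(n=400_000, seed=42)
        assert cumulative_scatter(seg).var() == pytest.approx(1.132, rel=0.05)

    def test_matches_elementwise_addition_oracle(self, rng):
        seg = make_segment(n=500, seed=9)
        expected = (
            seg.channels["scatter405"]
            + seg.channels["scatter488"]
            + seg.channels["scatter633"]
        )
        np.testing.assert_allclose(cumulative_scatter(seg), expected)

    def test_missing_scatter_channel_raises(self):
        seg = make_segment(n=100)
        del seg.channels["scatter633"]
        with pytest.raises(SchemaError):
            cumulative_scatter(seg)


class TestClotDetection:
    def test_constant_signal_is_clean(self):
        assert detect_clot(np.full(100, 2.5)) is False

    def test_injected_drift_detected(self, rng):
        x = rng.standard_normal(20_000) + 2.5 * np.sin(np.linspace(0, 3 * np.pi, 20_000))
        assert np.std(x, ddof=1) > 1.75
        assert detect_clot(x) is True

    def test_threshold_is_strict_inequality(self, rng):
        x = rng.standard_normal(5000)
        params = DetectionParams(clot_std_threshold=float(np.std(x, ddof=1)))
        assert detect_clot(x, params) is False


class TestClotCorrection:
    def test_clean_segment_untouched(self):
        seg = make_segment(n=5000, seed=1)
        out, report = correct_clot(seg)
        assert report.iterations == 0 and not report.detected
        for c in seg.channels:
            np.testing.assert_array_equal(out.channels[c], seg.channels[c])

    def test_ramp_drift_removed_mean_preserved(self, rng):
        n = 60_000
        seg = make_segment(n=n, seed=2)
        ramp = np.linspace(-5, 5, n)
        for c in ("scatter405", "scatter488", "scatter633"):
            seg.channels[c] = seg.channels[c] + ramp / 3 + 1.0
        before_mean = cumulative_scatter(seg).mean()
        out, report = correct_clot(seg)
        assert report.detected
        assert report.final_std < 1.75
        assert report.final_std <= report.initial_std
        assert abs(cumulative_scatter(out).mean() - before_mean) < 1e-6

    def test_unremovable_oscillation_stops_after_three_iterations(self):
        # high-frequency oscillation passes through a 500-point moving average
        n = 30_000
        t = np.arange(n)
        seg = make_segment(n=n, stds=(0.01, 0.01, 0.01), seed=3)
        for c in ("scatter405", "scatter488", "scatter633"):
            seg.channels[c] = seg.channels[c] + np.sin(2 * np.pi * t / 20)
        _, report = correct_clot(seg)
        assert report.iterations == 3
        assert report.final_std > 1.75

    def test_short_segment_shrinks_window_with_warning(self):
        seg = make_segment(n=200, seed=4)
        with pytest.warns(UserWarning, match="window"):
            correct_clot(seg)


class TestBandpass:
    def test_zero_in_zero_out(self):
        seg = make_segment(n=4000, stds=(0, 0, 0))
        out = bandpass_filter(seg)
        for c in ("scatter405", "scatter488", "scatter633"):
            np.testing.assert_allclose(out.channels[c], 0.0, atol=1e-12)

    def test_dc_offset_rejected(self):
        seg = make_segment(n=60_000, seed=5)
        seg.channels["scatter405"] = seg.channels["scatter405"] * 0 + 5.0
        out = bandpass_filter(seg)
        assert abs(out.channels["scatter405"].mean()) < 1e-3

    def test_stopband_attenuation_matches_analytic_butterworth(self):
        fs, n = 60_000.0, 120_000
        t = np.arange(n) / fs
        lo, hi, order = 50.0, 10_000.0, 2

        def warp(f):
            # bilinear-transform frequency warping of the digital design
            return fs / np.pi * np.tan(np.pi * f / fs)

        def mag2(f):
            # |H|^2 of an order-2 Butterworth band-pass at the warped
            # frequency; the zero-phase (forward-backward) application
            # makes the measured amplitude response equal to |H|^2
            w, w1, w2 = 2 * np.pi * warp(f), 2 * np.pi * warp(lo), 2 * np.pi * warp(hi)
            return 1.0 / (1.0 + ((w**2 - w1 * w2) / (w * (w2 - w1))) ** (2 * order))

        amps = {}
        for f in (1_000.0, 25_000.0):
            seg = make_segment(n=n, stds=(0, 0, 0))
            seg.channels["scatter405"] = np.sin(2 * np.pi * f * t)
            out = bandpass_filter(seg).channels["scatter405"][n // 4 : -n // 4]
            amps[f] = np.sqrt(2) * out.std()
        expected_ratio = mag2(25_000.0) / mag2(1_000.0)
        assert amps[25_000.0] / amps[1_000.0] == pytest.approx(expected_ratio, rel=0.05)

    def test_band_above_nyquist_rejected(self):
        seg = make_segment(n=1000, sample_rate=12_000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(seg)


class TestNormalize:
    def test_maps_span_to_unit_interval(self):
        seg = make_segment(n=100, seed=3)
        seg.channels["scatter405"] = np.linspace(-1, 3, 100)
        out = normalize_segment(seg)
        x = out.channels["scatter405"]
        assert x.min() == 0.0 and x.max() == 1.0

    def test_idempotent_on_unit_interval(self, rng):
        seg = make_segment(n=500, seed=6)
        once = normalize_segment(seg)
        twice = normalize_segment(once)
        for c in ("scatter405", "scatter488", "scatter633"):
            np.testing.assert_allclose(twice.channels[c], once.channels[c])

    def test_scale_invariant(self):
        seg = make_segment(n=500, seed=7)
        doubled = seg.copy()
        for c in ("scatter405", "scatter488", "scatter633"):
            doubled.channels[c] = doubled.channels[c] * 2
        a, b = normalize_segment(seg), normalize_segment(doubled)
        for c in ("scatter405", "scatter488", "scatter633"):
            np.testing.assert_allclose(a.channels[c], b.channels[c], atol=1e-12)

    def test_constant_channel_zeroed_with_warning(self):
        seg = make_segment(n=100, seed=8)
        seg.channels["scatter488"] = np.full(100, 3.3)
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_segment(seg)
        assert np.all(out.channels["scatter488"] == 0)


class TestHotellingT2:
    def test_observation_at_centroid_scores_zero(self):
        seg = make_segment(n=401, seed=9)
        # force sample 200 to equal the channel means
        for c in ("scatter405", "scatter488", "scatter633"):
            x = seg.channels[c]
            x[200] = (x.sum() - x[200]) / (len(x) - 1)
        t2 = hotelling_t2_trace(seg, DetectionParams(n_principal_components=3))
        assert t2[200] == pytest.approx(0.0, abs=1e-6)

    def test_all_components_equal_brute_force_mahalanobis(self):
        seg = make_segment(n=2000, seed=10)
        t2 = hotelling_t2_trace(seg, DetectionParams(n_principal_components=3))
        X = seg.scatter_matrix()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        oracle = np.einsum("ij,ij->i", Xc @ np.linalg.inv(cov), Xc)
        np.testing.assert_allclose(t2, oracle, atol=1e-8)

    def test_cluster_peak_exceeds_threshold_baseline_mostly_below(self):
        cfg = SimConfig(segment_duration=5.0, ctcc_rate=24.0, single_cell_rate=0,
                        clot_rate=0)
        segments, truth = simulate_day(cfg, 1, seed=30)
        seg = normalize_segment(bandpass_filter(segments[0]))
        t2 = hotelling_t2_trace(seg)
        inside = np.zeros(seg.n_samples, dtype=bool)
        for _, ev in truth.iterrows():
            inside[ev.start_index : ev.end_index] = True
            assert t2[ev.start_index : ev.end_index].max() > 10
        assert np.mean(t2[~inside] < 10) > 0.98

    def test_zero_variance_component_excluded_with_warning(self):
        seg = make_segment(n=300, stds=(0.4, 0.4, 0.4), seed=11)
        seg.channels["scatter633"] = seg.channels["scatter405"] * 2.0  # rank 2
        with pytest.warns(UserWarning, match="zero variance"):
            hotelling_t2_trace(seg, DetectionParams(n_principal_components=3))


class TestFindRois:
    def test_flat_trace_yields_nothing(self):
        assert find_rois(np.zeros(1000)) == []

    def test_triangular_excursion_has_analytic_bounds(self):
        t2 = np.zeros(300)
        t2[100:131] = np.linspace(0, 50, 31)
        t2[130:161] = np.linspace(50, 0, 31)
        events = find_rois(t2)
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_index == 130
        # value > 10 first at index 107 (value 11.67), last at 153
        assert ev.start_index == 107
        assert ev.end_index == 154
        assert ev.peak_t2 == pytest.approx(50.0)

    def test_two_maxima_in_one_run_become_single_event(self):
        t2 = np.zeros(200)
        t2[50:90] = 30.0
        t2[60] = 45.0
        t2[80] = 60.0
        events = find_rois(t2)
        assert len(events) == 1
        assert events[0].peak_index == 80

    def test_negative_trace_rejected(self):
        with pytest.raises(ValueError):
            find_rois(np.array([-1.0, 0.0, 5.0]))


class TestEqualizeHeights:
    def test_single_pulse_rescaled_to_unit_peak(self):
        x = 0.8 * np.exp(-0.5 * ((np.arange(51) - 25) / 6) ** 2)
        out = equalize_heights(x)
        np.testing.assert_allclose(out, x / 0.8)

    def test_shouldered_pulse_maxima_both_reach_one(self):
        x = np.concatenate([
            np.exp(-0.5 * ((np.arange(40) - 20) / 5) ** 2),
            0.4 * np.exp(-0.5 * ((np.arange(40) - 15) / 5) ** 2),
        ])
        out = equalize_heights(x)
        from deeppeak.roi_detect import _local_maxima

        peaks = _local_maxima(x)
        assert len(peaks) == 2
        np.testing.assert_allclose(out[peaks], 1.0, atol=1e-12)

    def test_pointwise_division_by_peak_to_peak_line(self):
        x = np.concatenate([
            np.exp(-0.5 * ((np.arange(30) - 15) / 4) ** 2),
            0.5 * np.exp(-0.5 * ((np.arange(30) - 14) / 4) ** 2),
        ])
        from deeppeak.roi_detect import _local_maxima

        p0, p1 = _local_maxima(x)
        out = equalize_heights(x)
        h0, h1 = x[p0], x[p1]
        for i in range(p0, p1 + 1):
            line = h0 + (h1 - h0) * (i - p0) / (p1 - p0)
            assert out[i] == pytest.approx(x[i] / line, abs=1e-12)
        np.testing.assert_allclose(out[: p0 + 1], x[: p0 + 1] / h0)
        np.testing.assert_allclose(out[p1:], x[p1:] / h1)

    @settings(deadline=None, max_examples=30)
    @given(
        amp2=st.floats(0.4, 0.9),
        w1=st.floats(2.5, 4.0),
        w2=st.floats(2.5, 4.0),
        sep=st.integers(25, 35),
    )
    def test_idempotent_on_smooth_shouldered_peaks(self, amp2, w1, w2, sep):
        # widths narrow relative to the separation so that dividing by the
        # peak-to-peak line cannot move a maximum by a whole sample
        t = np.arange(60)
        x = (
            np.exp(-0.5 * ((t - 14) / w1) ** 2)
            + amp2 * np.exp(-0.5 * ((t - 14 - sep) / w2) ** 2)
            + 1e-6
        )
        once = equalize_heights(x)
        twice = equalize_heights(once)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_all_zero_returned_unchanged_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = equalize_heights(np.zeros(10))
        assert np.all(out == 0)


class TestMeasureFwhm:
    def test_symmetric_triangle_closed_form(self):
        x = np.concatenate([np.linspace(0, 1, 21), np.linspace(1, 0, 21)[1:]])
        assert measure_fwhm(x, 20) == 20

    def test_gaussian_matches_analytic_width(self):
        x = np.exp(-0.5 * ((np.arange(101) - 50) / 5.0) ** 2)
        analytic = 2 * np.sqrt(2 * np.log(2)) * 5.0  # 11.77
        assert measure_fwhm(x, 50) == round(analytic)

    def test_rendered_two_cell_cluster_passes_gate(self):
        from deeppeak.simulate import render_peak

        p = render_peak("ctcc", 26, (1.0,))[:, 0]
        assert measure_fwhm(equalize_heights(p), int(np.argmax(p))) >= 17

    def test_no_crossing_clips_to_length_with_flag(self):
        x = np.full(9, 1.0)
        x[4] = 1.0
        fwhm, clipped = measure_fwhm(equalize_heights(x), 4, full_output=True)
        assert clipped and fwhm == 9


class TestWidthGate:
    def test_empty_in_empty_out(self):
        assert width_gate([]) == []

    def test_17_point_boundary_inclusive(self):
        events = [_roi(0, 5, 10, f) for f in (12, 16, 17, 30)]
        kept = width_gate(events)
        assert sorted(e.fwhm_samples for e in kept) == [17, 30]

    def test_pure_filter_subset_and_idempotent(self, rng):
        events = [_roi(i, i + 1, i + 40, int(f)) for i, f in
                  enumerate(rng.integers(1, 40, 30))]
        kept = width_gate(events)
        assert set(id(e) for e in kept) <= set(id(e) for e in events)
        assert width_gate(kept) == kept


class TestEndToEndDetection:
    def test_cluster_recovery_and_fluorescence_overlap(self):
        cfg = SimConfig(
            segment_duration=20.0, single_cell_rate=20.0, ctcc_rate=9.0, clot_rate=0,
            ctcc_size_distribution=(SizeCategory(0.5, 26, 40), SizeCategory(0.5, 40, 90)),
        )
        guard = int(3 * 60_000 / 50)
        recovered, total = 0, 0
        for seed in (101, 102):
            segments, truth = simulate_day(cfg, 1, seed=seed)
            seg = segments[0]
            rois, clot = detect_segment(seg)
            gfp = detect_gfp_rois(seg)
            assert not clot.detected
            ctcc = truth[
                (truth["kind"] == "ctcc")
                & (truth["physical_length_um"] >= 20)
                & (truth["start_index"] >= guard)
                & (truth["end_index"] <= seg.n_samples - guard)
            ]
            for _, ev in ctcc.iterrows():
                total += 1
                recovered += any(
                    r.start_index < ev.end_index and ev.start_index < r.end_index
                    for r in rois
                )
                assert any(
                    g.start_index < ev.end_index and ev.start_index < g.end_index
                    for g in gfp
                )
        assert total >= 3
        assert recovered == total

    def test_event_free_noise_yields_no_retained_rois(self):
        cfg = SimConfig(segment_duration=30.0, single_cell_rate=0, ctcc_rate=0,
                        clot_rate=0)
        segments, _ = simulate_day(cfg, 1, seed=207)
        rois, _ = detect_segment(segments[0])
        assert rois == []

    def test_gfp_channel_required(self):
        seg = make_segment(n=1000)
        del seg.channels["gfp525"]
        with pytest.raises(SchemaError):
            detect_gfp_rois(seg)

    def test_segment_without_events_has_empty_gfp_rois(self):
        cfg = SimConfig(segment_duration=5.0, single_cell_rate=0, ctcc_rate=0,
                        clot_rate=0)
        segments, _ = simulate_day(cfg, 1, seed=50)
        assert detect_gfp_rois(segments[0]) == []
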