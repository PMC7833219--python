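"""Segmentation and per-segment Hurst projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geostress import (
    SMSTimeSeries,
    complexity_track,
    estimate_hurst,
    generate_fgn,
    generate_piecewise_series,
    make_segmentation,
    stress_indicatrix,
)
from geostress.io import DataError


class TestSegmentation:
    def test_equal_boundaries(self):
        seg = make_segmentation(0, 100, 4)
        np.testing.assert_allclose(seg.boundaries, [0, 25, 50, 75, 100])

    @given(
        t0=st.floats(-1e3, 1e3),
        span=st.floats(1e-3, 1e6),
        k=st.integers(2, 500),
    )
    @settings(max_examples=50, derandomize=True)
    def test_intervals_cover_span_exactly(self, t0, span, k):
        seg = make_segmentation(t0, t0 + span, k)
        assert seg.k == k
        scale = max(1.0, abs(t0), span)
        assert abs(seg.lengths.sum() - span) <= 1e-9 * scale
        # equidistant with no drift from repeated addition; spacing errors
        # are bounded by rounding at the boundary magnitude, not the span
        np.testing.assert_allclose(seg.lengths, span / k, atol=1e-12 * scale, rtol=0)

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError, match="k"):
            make_segmentation(0, 100, 1)

    def test_half_open_segments_partition_samples(self):
        seg = make_segmentation(0, 8, 4)
        t = np.arange(9.0)
        counts = sum(seg.segment_mask(t, m).astype(int) for m in range(4))
        assert np.all(counts == 1)  # every sample in exactly one segment


class TestEstimateHurst:
    def test_white_noise_near_half(self):
        x = np.random.default_rng(0).normal(size=4096)
        assert 0.4 <= estimate_hurst(x) <= 0.6

    @pytest.mark.parametrize("method", ["rs", "dfa"])
    def test_persistent_fgn_recovered(self, method):
        x = generate_fgn(0.8, 4096, 1)
        assert 0.7 <= estimate_hurst(x, method=method) <= 0.9

    def test_constant_vector_flagged(self):
        assert np.isnan(estimate_hurst(np.full(4096, 2.0)))

    def test_short_segment_flagged(self):
        assert np.isnan(estimate_hurst(np.random.default_rng(0).normal(size=10)))

    @pytest.mark.parametrize("target", [0.3, 0.5, 0.7])
    def test_mean_recovery_within_tenth(self, target):
        est = [estimate_hurst(generate_fgn(target, 4096, s)) for s in range(20)]
        assert abs(np.mean(est) - target) <= 0.1

    @given(
        a=st.floats(-100, 100),
        b=st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3),
    )
    @settings(max_examples=25, derandomize=True)
    def test_affine_invariance(self, a, b):
        x = generate_fgn(0.6, 1024, 7)
        h0 = estimate_hurst(x)
        h1 = estimate_hurst(a + b * x)
        assert h1 == pytest.approx(h0, abs=1e-6)

    def test_codomain_clipped(self):
        # a strongly trending signal pushes the raw slope above 1
        x = np.cumsum(np.ones(512)) + np.random.default_rng(0).normal(0, 1e-3, 512)
        h = estimate_hurst(x)
        assert 0 < h <= 1.0


class TestComplexityTrack:
    def test_alternating_profile_recovered(self):
        profile = [(1, 0.3), (1, 0.7)] * 4
        s = generate_piecewise_series(profile, 2048, 3)
        seg = make_segmentation(s.times[0], s.times[-1], 8)
        track = complexity_track(s, seg)
        expect_low = np.array([True, False] * 4)
        hits = ((track.values < 0.5) == expect_low).sum()
        assert hits >= 7

    def test_sample_count_bookkeeping(self):
        s = generate_piecewise_series([(4, 0.5)], 256, 0)
        seg = make_segmentation(s.times[0], s.times[-1], 4)
        track = complexity_track(s, seg)
        assert track.counts.sum() == 1024
        assert np.all(np.abs(track.counts - 256) <= 1)

    def test_fig6_scale_segment_size_accepted(self):
        # ~225 samples per segment is a supported working scale
        s = generate_piecewise_series([(8, 0.6)], 225, 1, dt=30.0)
        seg = make_segmentation(s.times[0], s.times[-1], 8)
        track = complexity_track(s, seg)
        assert track.n_flagged == 0

    def test_nonuniform_series_rejected(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 100, 200))
        s = SMSTimeSeries("HRV", t, np.random.default_rng(1).normal(size=200))
        seg = make_segmentation(0, 100, 4)
        with pytest.raises(ValueError, match="uniform"):
            complexity_track(s, seg)

    def test_constant_segments_carried_as_flagged_gaps(self):
        s = generate_piecewise_series([(8, 0.5)], 256, 0)
        s.values[:512] = 5.0  # first two segments constant -> undefined H
        seg = make_segmentation(s.times[0], s.times[-1], 8)
        track = complexity_track(s, seg)
        assert track.n_flagged == 2
        assert np.all(~track.valid[:2]) and np.all(track.valid[2:])

    def test_too_few_valid_segments_is_error(self):
        s = generate_piecewise_series([(2, 0.5)], 100, 0)
        seg = make_segmentation(s.times[0], s.times[-1], 2)
        with pytest.raises(DataError):
            complexity_track(s, seg, min_samples=150)


class TestStressIndicatrix:
    def test_identical_channels_identical_tracks(self):
        s = generate_piecewise_series([(4, 0.6)], 512, 2)
        seg = make_segmentation(s.times[0], s.times[-1], 4)
        ind = stress_indicatrix(s, s, s, seg)
        np.testing.assert_array_equal(ind.hrv.values, ind.sf.values)
        np.testing.assert_array_equal(ind.hrv.values, ind.spo2.values)

    def test_codomain(self, rest_recording):
        hrv, sf, spo2 = (rest_recording[c] for c in ("HRV", "SF", "SpO2"))
        seg = make_segmentation(hrv.times[0], hrv.times[-1], 8)
        ind = stress_indicatrix(hrv, sf, spo2, seg)
        pts = ind.points()
        valid = np.isfinite(pts)
        assert np.all(pts[valid] > 0) and np.all(pts[valid] <= 1)

    def test_known_profiles_recovered(self):
        from geostress import SyntheticSpec, generate_sms_dataset

        spec = SyntheticSpec(
            profiles={
                "HRV": [(4, 0.3), (4, 0.7)],
                "SF": [(8, 0.5)],
                "SpO2": [(4, 0.7), (4, 0.4)],
            },
            n_per_segment=2048,
            seed=9,
        )
        data = generate_sms_dataset(spec)
        seg = make_segmentation(0, data["HRV"].duration, 8)
        ind = stress_indicatrix(data["HRV"], data["SF"], data["SpO2"], seg)
        for track, profile in (
            (ind.hrv, [0.3] * 4 + [0.7] * 4),
            (ind.sf, [0.5] * 8),
            (ind.spo2, [0.7] * 4 + [0.4] * 4),
        ):
            err = np.abs(track.values - np.array(profile)).mean()
            assert err <= 0.15

    def test_misaligned_grids_rejected(self):
        a = generate_piecewise_series([(2, 0.5)], 256, 0)
        b = generate_piecewise_series([(2, 0.5)], 256, 1, dt=2.0)
        seg = make_segmentation(a.times[0], a.times[-1], 2)
        with pytest.raises(ValueError):
            stress_indicatrix(a, a, b, seg)
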