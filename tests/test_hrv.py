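"""HRV metric and sliding-window tests against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvscrub.hrv import (
    BeatTimeSeries,
    IBISeries,
    beats_to_ibi,
    clean_ibi,
    consistency_ratio,
    cvi,
    overall_hrv,
    rmssd,
    sliding_hrv,
    window_selection_report,
)


def make_beats(times, subject="s01", session="A"):
    return BeatTimeSeries(subject_id=subject, session_id=session, beat_times=np.asarray(times, float))


class TestBeatsToIbi:
    @pytest.mark.parametrize(
        "times, intervals, anchors",
        [
            ([1.0, 1.8, 2.6], [800.0, 800.0], [1.8, 2.6]),
            ([0.0, 0.75, 1.6], [750.0, 850.0], [0.75, 1.6]),
        ],
    )
    def test_direct_differencing(self, times, intervals, anchors):
        ibi = beats_to_ibi(make_beats(times))
        np.testing.assert_allclose(ibi.intervals, intervals)
        np.testing.assert_allclose(ibi.anchor_times, anchors)

    def test_non_monotonic_rejected(self):
        with pytest.raises(ValueError, match="non-monotonic"):
            make_beats([2.0, 1.0])

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            make_beats([1.0])

    def test_interval_sum_equals_span(self):
        rng = np.random.default_rng(7)
        times = np.cumsum(rng.uniform(0.6, 1.2, 50))
        ibi = beats_to_ibi(make_beats(times))
        assert ibi.intervals.sum() == pytest.approx(1000.0 * (times[-1] - times[0]))


class TestCleanIbi:
    def test_clean_series_unchanged(self):
        ibi = IBISeries(intervals=[800.0] * 5, anchor_times=np.arange(5) * 0.8 + 0.8)
        out = clean_ibi(ibi)
        np.testing.assert_allclose(out.intervals, ibi.intervals)
        assert out.cleaned

    def test_single_ectopic_interpolated(self):
        ibi = IBISeries(
            intervals=[800.0, 800.0, 1600.0, 800.0, 800.0],
            anchor_times=[0.8, 1.6, 3.2, 4.0, 4.8],
        )
        out = clean_ibi(ibi, ectopic_threshold=0.2)
        # equal neighbours -> replacement 800, then zero residual trend
        np.testing.assert_allclose(out.intervals, [800.0] * 5, atol=1e-9)

    def test_linear_trend_removed_mean_preserved(self):
        # pure 700 -> 900 ms ramp; least-squares fit oracle says the detrended
        # series is flat at the original mean of 800 ms
        t = np.linspace(1, 40, 40)
        ramp = np.linspace(700.0, 900.0, 40)
        slope, intercept = np.polyfit(t, ramp, 1)  # oracle fit
        expected = ramp - (slope * t + intercept) + ramp.mean()
        out = clean_ibi(IBISeries(intervals=ramp, anchor_times=t))
        np.testing.assert_allclose(out.intervals, expected, atol=1e-9)
        np.testing.assert_allclose(out.intervals, 800.0, atol=1e-9)

    def test_all_ectopic_is_unusable(self):
        # two-point series: the local median is their midpoint, so both
        # intervals deviate beyond the threshold
        ibi = IBISeries(intervals=[500.0, 900.0], anchor_times=[1.0, 1.9])
        with pytest.raises(ValueError, match="unusable"):
            clean_ibi(ibi, ectopic_threshold=0.2)

    def test_idempotent_on_clean_series(self):
        rng = np.random.default_rng(3)
        iv = 800 + rng.normal(0, 20, 60)
        once = clean_ibi(IBISeries(intervals=iv, anchor_times=np.cumsum(iv) / 1000))
        twice = clean_ibi(once)
        np.testing.assert_allclose(twice.intervals, once.intervals, atol=1e-9)


class TestRmssd:
    @pytest.mark.parametrize(
        "intervals, expected",
        [
            ([800, 800, 800], 0.0),
            ([800, 810], 10.0),
            ([800, 810, 790], np.sqrt((10**2 + 20**2) / 2)),  # 15.811...
        ],
    )
    def test_hand_cases(self, intervals, expected):
        assert rmssd(intervals) == pytest.approx(expected, abs=1e-12)

    def test_undefined_below_two(self):
        assert np.isnan(rmssd([800.0]))

    @given(st.lists(st.floats(400, 1500), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_reversal_and_translation_invariance(self, intervals):
        x = np.array(intervals)
        assert rmssd(x[::-1]) == pytest.approx(rmssd(x), rel=1e-9, abs=1e-9)
        assert rmssd(x + 123.4) == pytest.approx(rmssd(x), rel=1e-9, abs=1e-6)


class TestCvi:
    def test_constant_series_undefined(self):
        assert np.isnan(cvi([800.0] * 10))

    def test_strict_alternation_degenerate(self):
        # successive sums are constant -> SD2 = 0 -> undefined by contract
        assert np.isnan(cvi([800.0, 850.0] * 5))

    def test_lorenz_axes_oracle(self):
        # direct Lorenz-plot computation as oracle on a jittered alternation:
        # alternation puts variability on the transverse axis, so SD1 > SD2
        rng = np.random.default_rng(0)
        x = np.array([800.0, 850.0] * 10) + rng.normal(0, 2, 20)
        d = (x[1:] - x[:-1]) / np.sqrt(2)
        s = (x[1:] + x[:-1]) / np.sqrt(2)
        sd1, sd2 = np.std(d, ddof=1), np.std(s, ddof=1)
        assert sd1 > sd2
        assert cvi(x) == pytest.approx(np.log10(16 * sd1 * sd2), abs=1e-12)

    def test_scale_property(self):
        # multiplying intervals by 10 scales both axes by 10: CVI rises by 2
        rng = np.random.default_rng(1)
        x = 800 + rng.normal(0, 30, 40)
        assert cvi(10 * x) - cvi(x) == pytest.approx(2.0, abs=1e-9)


class TestSlidingHrv:
    def test_constant_ibi_all_zero(self):
        iv = np.full(200, 800.0)
        ibi = IBISeries(intervals=iv, anchor_times=np.cumsum(iv) / 1000)
        tv = sliding_hrv(ibi, "rmssd", 16.0, 2.2, 60)
        assert np.all(tv.values[tv.defined] == 0)
        assert tv.defined.all()

    def test_short_recording_leading_undefined(self):
        # recording starts at 100 s: early windows hold no intervals
        ibi = IBISeries(intervals=[800.0, 820.0, 790.0], anchor_times=[100.0, 100.8, 101.6])
        tv = sliding_hrv(ibi, "rmssd", 16.0, 2.2, 50)
        assert not tv.defined[:40].any()
        assert tv.defined.any()

    @pytest.mark.parametrize("metric", ["rmssd", "cvi"])
    def test_matches_bruteforce_window_membership(self, metric):
        # half-open windows centred on each TR, membership by anchor time
        from hrvscrub.hrv import MIN_INTERVALS, _METRIC_FUNCS

        rng = np.random.default_rng(42)
        for _ in range(20):
            iv = rng.uniform(600, 1100, rng.integers(30, 300))
            ibi = IBISeries(intervals=iv, anchor_times=np.cumsum(iv) / 1000)
            tr, w, n_vol = 2.2, rng.uniform(4, 30), 40
            tv = sliding_hrv(ibi, metric, w, tr, n_vol)
            for i in range(n_vol):
                c = (i + 0.5) * tr
                members = iv[(ibi.anchor_times >= c - w / 2) & (ibi.anchor_times < c + w / 2)]
                if members.size >= MIN_INTERVALS[metric]:
                    expected = _METRIC_FUNCS[metric](members)
                    if np.isnan(expected):
                        assert np.isnan(tv.values[i])
                    else:
                        assert tv.values[i] == expected
                else:
                    assert np.isnan(tv.values[i])

    def test_state_contrast_visible(self):
        # alternating calm/variable IBI segments: windowed RMSSD separates them
        rng = np.random.default_rng(5)
        calm = 800 + rng.normal(0, 5, 150)
        wild = 900 + rng.normal(0, 60, 150)
        iv = np.concatenate([calm, wild])
        ibi = IBISeries(intervals=iv, anchor_times=np.cumsum(iv) / 1000)
        n_vol = int(ibi.anchor_times[-1] / 2.2)
        tv = sliding_hrv(ibi, "rmssd", 16.0, 2.2, n_vol)
        mid = int(calm.sum() / 1000 / 2.2)
        assert np.nanmean(tv.values[5:mid - 5]) < np.nanmean(tv.values[mid + 5:-5])


class TestConsistencyRatio:
    def test_identity_and_half(self):
        tv = [
            type("TV", (), {"values": np.array([10.0, 10.0])})(),
        ]
        assert consistency_ratio(tv, [10.0]) == pytest.approx(1.0)
        assert consistency_ratio(tv, [20.0]) == pytest.approx(0.5)

    def test_zero_denominator_errors(self):
        tv = [type("TV", (), {"values": np.array([1.0])})()]
        with pytest.raises(ValueError):
            consistency_ratio(tv, [0.0])


class TestWindowSelection:
    def _tiny_cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        ibis = {}
        for s in ("s01", "s02", "s03"):
            scale = rng.uniform(0.8, 1.3)
            for ses in ("A", "B"):
                iv = 800 + rng.normal(0, 30 * scale, 160)
                ibis[(s, ses)] = IBISeries(intervals=iv, anchor_times=np.cumsum(iv) / 1000)
        return ibis

    def test_single_qualifying_candidate_chosen(self):
        ibis = self._tiny_cohort()
        rep = window_selection_report([24.0], ibis, tr=2.2, n_volumes=50, consistency_min=0.5)
        assert rep.chosen_length == 24.0

    def test_no_qualifier_warns(self):
        ibis = self._tiny_cohort()
        rep = window_selection_report([24.0], ibis, tr=2.2, n_volumes=50, consistency_min=10.0)
        assert rep.chosen_length is None
        assert rep.warning is not None

    def test_chosen_window_meets_consistency_band(self):
        # realistic synthetic IBI cohort: the chosen window's time-varying
        # HRV must be highly consistent with whole-scan HRV (ratio > 0.95)
        from hrvscrub.hrv import DEFAULT_WINDOW_CANDIDATES, beats_to_ibi, clean_ibi
        from hrvscrub.synthetic import SimulationConfig, simulate_sessions

        cohort = simulate_sessions(SimulationConfig(seed=3, n_subjects=8))
        ibis = {k: clean_ibi(beats_to_ibi(cohort.beats[k])) for k in cohort.keys}
        rep = window_selection_report(
            DEFAULT_WINDOW_CANDIDATES, ibis, cohort.tr, cohort.n_volumes
        )
        assert rep.chosen_length is not None
        assert rep.consistency_ratio[rep.chosen_length] > 0.95
        assert np.isfinite(rep.scan_wise_icc[rep.chosen_length])

    def test_reproducible(self):
        a = window_selection_report([8.0, 16.0], self._tiny_cohort(3), 2.2, 50)
        b = window_selection_report([8.0, 16.0], self._tiny_cohort(3), 2.2, 50)
        assert a.consistency_ratio == b.consistency_ratio
        assert a.scan_wise_icc == b.scan_wise_icc
        assert a.chosen_length == b.chosen_length


def test_overall_hrv_matches_metric_on_full_series():
    iv = np.array([800.0, 830.0, 790.0, 820.0])
    ibi = IBISeries(intervals=iv, anchor_times=np.cumsum(iv) / 1000)
    assert overall_hrv(ibi, "rmssd") == rmssd(iv)
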