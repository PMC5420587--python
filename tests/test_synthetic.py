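"""Synthetic-cohort generator: timelines, cardiac calibration, mechanism."""

import numpy as np
import pytest
from scipy import stats

from hrvscrub.censoring import alertness_survival, select_volumes
from hrvscrub.hrv import beats_to_ibi, rmssd, sliding_hrv
from hrvscrub.synthetic import SimulationConfig, simulate_ibi, simulate_sessions, simulate_timeline


class TestTimeline:
    def test_zero_hazard_all_wake(self):
        cfg = SimulationConfig(hazard_intercept=0.0, hazard_slope=0.0, n_volumes=50)
        tl = simulate_timeline(cfg, np.random.default_rng(0))
        assert not tl.any()

    def test_unit_hazard_drowsy_from_second_volume(self):
        cfg = SimulationConfig(hazard_intercept=1.0, hazard_slope=0.0, n_volumes=10)
        tl = simulate_timeline(cfg, np.random.default_rng(0))
        assert not tl[0]
        assert tl[1:].all()

    def test_no_recovery(self):
        cfg = SimulationConfig(n_volumes=215, hazard_slope=5e-4)
        tl = simulate_timeline(cfg, np.random.default_rng(3))
        onset = np.argmax(tl) if tl.any() else None
        if onset is not None:
            assert tl[onset:].all()

    def test_cohort_survival_decreases(self):
        # default config: some subjects accumulate 5 consecutive sleepy
        # volumes before the scan ends, so the survival curve must drop
        cohort = simulate_sessions(SimulationConfig(seed=11))
        masks = []
        for s in cohort.subjects:
            ibi = beats_to_ibi(cohort.beats[(s, "A")])
            tv = sliding_hrv(ibi, "rmssd", 16.0, cohort.tr, cohort.n_volumes)
            masks.append(select_volumes(tv, "sleepy", 0.5))
        curve = alertness_survival(masks, dropout_run=5)
        assert curve.counts[0] == len(cohort.subjects)
        assert np.all(np.diff(curve.counts) <= 0)
        assert curve.counts[-1] < len(cohort.subjects)


class TestSimulateIbi:
    @pytest.mark.parametrize("drowsy, target", [(False, 30.0), (True, 60.0)])
    def test_rmssd_calibrated_within_20pct(self, drowsy, target):
        cfg = SimulationConfig()
        timeline = np.full(cfg.n_volumes, drowsy, dtype=bool)
        beats = simulate_ibi(cfg, timeline, np.random.default_rng(5))
        empirical = rmssd(beats_to_ibi(beats).intervals)
        assert abs(empirical - target) / target < 0.20

    def test_mean_ibi_state_dependent(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(6)
        wake = beats_to_ibi(simulate_ibi(cfg, np.zeros(cfg.n_volumes, bool), rng))
        drowsy = beats_to_ibi(simulate_ibi(cfg, np.ones(cfg.n_volumes, bool), rng))
        assert wake.intervals.mean() == pytest.approx(800, rel=0.05)
        assert drowsy.intervals.mean() == pytest.approx(900, rel=0.05)

    def test_windowed_rmssd_separates_states(self):
        # mixed timeline: drowsy windows carry significantly higher RMSSD
        cfg = SimulationConfig(n_volumes=200)
        timeline = np.zeros(200, bool)
        timeline[100:] = True
        beats = simulate_ibi(cfg, timeline, np.random.default_rng(7))
        tv = sliding_hrv(beats_to_ibi(beats), "rmssd", 16.0, cfg.tr, 200)
        wake_vals = tv.values[10:90]
        drowsy_vals = tv.values[110:190]
        stat = stats.mannwhitneyu(drowsy_vals, wake_vals, alternative="greater")
        assert stat.pvalue < 1e-6

    def test_beats_cover_widest_window(self):
        cfg = SimulationConfig(n_volumes=100)
        beats = simulate_ibi(cfg, np.zeros(100, bool), np.random.default_rng(8))
        assert beats.beat_times[-1] >= 100 * cfg.tr + 25.0


class TestSimulateSessions:
    def test_deterministic_given_seed(self):
        a = simulate_sessions(SimulationConfig(n_subjects=3, n_volumes=60, n_rois=8, seed=5))
        b = simulate_sessions(SimulationConfig(n_subjects=3, n_volumes=60, n_rois=8, seed=5))
        for key in a.keys:
            np.testing.assert_array_equal(a.roits[key].values, b.roits[key].values)
            np.testing.assert_array_equal(a.beats[key].beat_times, b.beats[key].beat_times)
            np.testing.assert_array_equal(a.timelines[key], b.timelines[key])

    def test_duplicate_sessions_exact_copy(self):
        cohort = simulate_sessions(
            SimulationConfig(n_subjects=3, n_volumes=60, n_rois=8, seed=2, duplicate_sessions=True)
        )
        for s in cohort.subjects:
            np.testing.assert_array_equal(
                cohort.roits[(s, "A")].values, cohort.roits[(s, "B")].values
            )

    def test_partition_labels_every_roi(self):
        cohort = simulate_sessions(SimulationConfig(n_subjects=2, n_volumes=60, n_rois=12, seed=0))
        assert set(cohort.partition) == set(cohort.roi_labels)
        assert len(set(cohort.partition.values())) == cohort.config.n_modules

    def _between_subject_sd(self, cfg):
        """SD across subjects of wake-volume mean connectivity."""
        cohort = simulate_sessions(cfg)
        means = []
        for s in cohort.subjects:
            ts = cohort.roits[(s, "A")]
            wake = ~cohort.timelines[(s, "A")]
            if wake.sum() < 10:
                continue
            r = np.corrcoef(ts.values[:, wake])
            iu = np.triu_indices(ts.n_rois, 1)
            means.append(r[iu].mean())
        return np.std(means)

    def test_trait_range_controls_between_subject_variance(self):
        # widening the global-share trait range spreads subjects apart
        sds = [
            self._between_subject_sd(
                SimulationConfig(
                    n_subjects=12, n_volumes=120, n_rois=16, seed=4,
                    global_share_range=(0.10, 0.10 + w),
                    module_coupling_range=(0.05, 0.2),
                )
            )
            for w in (0.01, 0.2, 0.5)
        ]
        assert sds[0] < sds[1] < sds[2]

    def test_drowsy_state_erases_subject_differences(self):
        # mechanism: drowsy-volume connectivity converges across subjects
        cfg = SimulationConfig(n_subjects=12, n_volumes=215, n_rois=16, seed=9, hazard_slope=5e-4)
        cohort = simulate_sessions(cfg)
        wake_means, drowsy_means = [], []
        for s in cohort.subjects:
            ts = cohort.roits[(s, "A")]
            tl = cohort.timelines[(s, "A")]
            iu = np.triu_indices(ts.n_rois, 1)
            if (~tl).sum() >= 20 and tl.sum() >= 20:
                wake_means.append(np.corrcoef(ts.values[:, ~tl])[iu].mean())
                drowsy_means.append(np.corrcoef(ts.values[:, tl])[iu].mean())
        assert len(wake_means) >= 5
        assert np.std(drowsy_means) < np.std(wake_means)

    def test_ablation_removes_state_contrast(self):
        # drowsy_perturbation = 0: drowsy blocks share the wake distribution
        cfg = SimulationConfig(
            n_subjects=6, n_volumes=215, n_rois=16, seed=10,
            drowsy_perturbation=0.0, hazard_slope=5e-4,
        )
        cohort = simulate_sessions(cfg)
        wake_m, drowsy_m = [], []
        for key in cohort.keys:
            ts, tl = cohort.roits[key], cohort.timelines[key]
            iu = np.triu_indices(ts.n_rois, 1)
            if (~tl).sum() >= 30 and tl.sum() >= 30:
                wake_m.append(np.corrcoef(ts.values[:, ~tl])[iu].mean())
                drowsy_m.append(np.corrcoef(ts.values[:, tl])[iu].mean())
        assert len(wake_m) >= 4
        # paired difference consistent with zero
        diff = np.array(wake_m) - np.array(drowsy_m)
        assert abs(diff.mean()) < 3 * diff.std(ddof=1) / np.sqrt(diff.size) + 0.02
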