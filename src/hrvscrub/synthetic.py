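"""Synthetic two-session cohorts with state-dependent cardiac and ROI signals.

The generator produces everything the analysis consumes, with the statistical
structure the method assumes baked in and tunable:

* a per-volume sleep timeline (wake -> drowsy, onset hazard growing linearly
  with scan time, no recovery by default), emulating the progressive loss of
  alertness over a resting-state scan;
* beat times whose interbeat intervals lengthen and become more variable in
  the drowsy state (mean IBI ~900 ms vs ~800 ms awake; RMSSD calibrated to
  the wake/drowsy targets), so the sliding-window HRV genuinely indexes the
  latent state;
* ROI time series with two stable subject traits that give scan-level
  summary measures something to be reliable about — a global-signal share
  (the subject's overall connectivity level) and a module-coupling strength
  (how strongly ROIs within a network co-fluctuate, the subject's triangle
  density) — on top of a subject-specific latent loading pattern shared by
  both sessions;
* a drowsy state that replaces the subject's own structure with a
  cohort-wide pattern (global synchronisation, no subject information) under
  inflated observation noise — the mechanism by which sleep erodes
  between-subject differences and hence test-retest reliability.

With ``drowsy_perturbation = 0`` the drowsy state is statistically identical
to wake and the three censoring conditions become indistinguishable, the
ablation control for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .connectivity import ROITimeSeriesMatrix
from .hrv import BeatTimeSeries

__all__ = [
    "SimulationConfig",
    "Cohort",
    "simulate_timeline",
    "simulate_ibi",
    "simulate_sessions",
]

# AR(1) coefficient of the standardized IBI deviation process; with phi = 0.5
# the stationary RMSSD equals the per-state deviation SD exactly.
_IBI_AR_PHI = 0.5
_IBI_FLOOR_MS = 400.0


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic cohort.

    Defaults mirror the analysed cohort: 17 subjects, 2 sessions, 215 volumes
    at TR 2.2 s. RMSSD targets (ms) are typical adult values for quiet wake
    vs drowsiness; ``drowsy_rmssd_target`` must exceed the wake target (HRV
    rises at sleep onset), and each subject carries stable log-normal scales
    on both cardiac parameters so HRV itself is a reliable trait.

    ROI signals are built per volume as

        x_i = sqrt(c) g + sqrt(lam) h_m(i) + sqrt(1 - c - lam) pattern_i

    with unit variance per ROI: ``g`` a global factor, ``h_m`` one factor per
    module (network), ``pattern_i`` a normalized subject-specific latent
    loading mix. The subject traits are ``c`` (global-signal share, drawn
    once per subject from ``global_share_range``) and ``lam`` (module
    coupling, from ``module_coupling_range``). Drowsy volumes blend toward a
    sleep state with its own global share and module coupling
    (``sleep_global_share``, ``sleep_module_coupling``) built on a cohort-wide
    loading pattern, scaled by an inflated noise factor; ``drowsy_perturbation``
    in [0, 1] interpolates between wake statistics (0, ablation) and the full
    sleep state (1, default).
    """

    n_subjects: int = 17
    n_volumes: int = 215
    n_rois: int = 32
    tr: float = 2.2
    wake_ibi_mean: float = 800.0
    drowsy_ibi_mean: float = 900.0
    wake_rmssd_target: float = 30.0
    drowsy_rmssd_target: float = 60.0
    hazard_intercept: float = 0.0
    hazard_slope: float = 8e-5  # per volume, drowsy-onset hazard = a + b*v
    subject_rmssd_sd: float = 0.3  # log-SD of the stable per-subject RMSSD scale
    subject_ibi_sd: float = 0.05  # log-SD of the stable per-subject mean-IBI scale
    n_latent: int = 5
    n_modules: int = 4
    subject_signature_strength: float = 1.0
    global_share_range: tuple = (0.02, 0.35)
    module_coupling_range: tuple = (0.05, 0.55)
    sleep_global_share: float = 0.2
    sleep_module_coupling: float = 0.05
    session_noise: float = 0.7
    drowsy_noise_factor: float = 1.5  # noise multiplier in the full sleep state
    drowsy_perturbation: float = 1.0
    duplicate_sessions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_volumes, self.n_rois, self.n_latent, self.n_modules) < 1:
            raise ValueError("counts must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.drowsy_rmssd_target <= self.wake_rmssd_target:
            raise ValueError("drowsy RMSSD target must exceed the wake target")
        if not (0.0 <= self.drowsy_perturbation <= 1.0):
            raise ValueError("drowsy_perturbation must lie in [0, 1]")
        c_hi = self.global_share_range[1]
        lam_hi = self.module_coupling_range[1]
        if c_hi + lam_hi >= 1.0 or min(self.global_share_range[0], self.module_coupling_range[0]) < 0:
            raise ValueError("variance shares must be nonnegative and sum below 1")


@dataclass(frozen=True)
class Cohort:
    """A complete two-session cohort: beats, ROI tables and ground truth."""

    tr: float
    n_volumes: int
    subjects: tuple
    sessions: tuple
    beats: Mapping[tuple, BeatTimeSeries]
    roits: Mapping[tuple, ROITimeSeriesMatrix]
    timelines: Mapping[tuple, np.ndarray] = field(default_factory=dict)
    partition: Mapping[str, str] | None = None  # roi_label -> network name
    config: SimulationConfig | None = None

    @property
    def keys(self) -> list[tuple]:
        return [(s, ses) for s in self.subjects for ses in self.sessions]

    @property
    def roi_labels(self) -> tuple:
        return self.roits[self.keys[0]].roi_labels


def simulate_timeline(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-volume wake/drowsy states from a first-order onset chain.

    The first volume is wake; a wake volume transitions into drowsiness at
    volume v with probability clip(hazard_intercept + hazard_slope * v, 0, 1)
    and never recovers. Returns a boolean array, True = drowsy.
    """
    drowsy = np.zeros(cfg.n_volumes, dtype=bool)
    hazard = np.clip(
        cfg.hazard_intercept + cfg.hazard_slope * np.arange(cfg.n_volumes), 0.0, 1.0
    )
    draws = rng.random(cfg.n_volumes)
    for v in range(1, cfg.n_volumes):
        drowsy[v] = drowsy[v - 1] or draws[v] < hazard[v]
    return drowsy


def simulate_ibi(
    cfg: SimulationConfig,
    timeline: np.ndarray,
    rng: np.random.Generator,
    subject_id: str = "sim",
    session_id: str = "A",
) -> BeatTimeSeries:
    """Beat times with state-dependent mean IBI and RMSSD.

    Intervals follow interval_n = mu(state) + sd(state) * z_n where z is a
    standardized AR(1) with phi = 0.5, so the within-state RMSSD equals the
    state's target SD. Intervals reflect at a 400 ms floor. Beats extend 30 s
    past the scan end so the widest sliding window stays populated; beyond
    the scan the last volume's state persists.
    """
    scan_end = cfg.n_volumes * cfg.tr
    horizon = scan_end + 30.0
    phi = _IBI_AR_PHI
    innov_sd = np.sqrt(1.0 - phi**2)
    t = 0.0
    z = rng.normal()
    times = [0.0]
    while t < horizon:
        vol = min(int(t // cfg.tr), cfg.n_volumes - 1)
        if timeline[vol]:
            mu, sd = cfg.drowsy_ibi_mean, cfg.drowsy_rmssd_target
        else:
            mu, sd = cfg.wake_ibi_mean, cfg.wake_rmssd_target
        z = phi * z + innov_sd * rng.normal()
        interval = mu + sd * z
        if interval < _IBI_FLOOR_MS:
            interval = 2 * _IBI_FLOOR_MS - interval  # reflect at the floor
        t += interval / 1000.0
        times.append(t)
    return BeatTimeSeries(
        subject_id=subject_id, session_id=session_id, beat_times=np.asarray(times)
    )


def _unit_pattern(loadings: np.ndarray, sigma: float, factors: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Latent-loading mix plus noise, normalised to unit variance per ROI."""
    raw = loadings @ factors + sigma * eps
    sd = np.sqrt((loadings**2).sum(axis=1) + sigma**2)
    return raw / sd[:, None]


def _state_block(
    cfg: SimulationConfig,
    modules: np.ndarray,
    loadings: np.ndarray,
    c: float,
    lam: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One session-length sample of a state's ROI signal, unit variance."""
    k, T, n = cfg.n_latent, cfg.n_volumes, cfg.n_rois
    g = rng.normal(size=(1, T))
    h = rng.normal(size=(cfg.n_modules, T))
    factors = rng.normal(size=(k, T))
    eps = rng.normal(size=(n, T))
    pattern = _unit_pattern(loadings, cfg.session_noise, factors, eps)
    return np.sqrt(c) * g + np.sqrt(lam) * h[modules] + np.sqrt(1.0 - c - lam) * pattern


def _roi_session(
    cfg: SimulationConfig,
    modules: np.ndarray,
    loadings: np.ndarray,
    sleep_loadings: np.ndarray,
    c_subj: float,
    lam_subj: float,
    timeline: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one session's n_rois x n_volumes matrix.

    Wake volumes use the subject's own traits and loading pattern; drowsy
    volumes interpolate (by ``drowsy_perturbation``) toward the cohort-wide
    sleep state with inflated noise. Both state blocks are drawn for the full
    session and the timeline picks per volume, so the ablation (p = 0) makes
    the drowsy block distributionally identical to wake.
    """
    p = cfg.drowsy_perturbation
    c_d = (1 - p) * c_subj + p * cfg.sleep_global_share
    lam_d = (1 - p) * lam_subj + p * cfg.sleep_module_coupling
    load_d = (1 - p) * loadings + p * sleep_loadings
    scale_d = 1.0 + p * (cfg.drowsy_noise_factor - 1.0)
    wake = _state_block(cfg, modules, loadings, c_subj, lam_subj, rng)
    drowsy = scale_d * _state_block(cfg, modules, load_d, c_d, lam_d, rng)
    return np.where(timeline[None, :], drowsy, wake)


def simulate_sessions(cfg: SimulationConfig) -> Cohort:
    """Generate the full two-session cohort, a pure function of the config.

    Every subject carries stable traits (global-signal share, module
    coupling, cardiac scales, latent signature) shared by both sessions;
    sessions differ only in their noise realisation and sleep timeline. With
    ``duplicate_sessions`` the second session is an exact copy of the first
    (the degenerate ICC = 1 check).
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_latent
    modules = np.arange(cfg.n_rois) % cfg.n_modules
    base = rng.normal(size=(cfg.n_rois, k)) / np.sqrt(k)
    sleep = rng.normal(size=(cfg.n_rois, k)) / np.sqrt(k)
    subjects = tuple(f"s{i + 1:02d}" for i in range(cfg.n_subjects))
    sessions = ("A", "B")
    roi_labels = tuple(f"roi{i + 1:03d}" for i in range(cfg.n_rois))
    partition = {lab: f"net{modules[i] + 1}" for i, lab in enumerate(roi_labels)}

    beats: dict = {}
    roits: dict = {}
    timelines: dict = {}
    for subj in subjects:
        # stable cardiac traits: subjects keep their own HRV level and heart
        # rate across sessions, the source of tv-HRV test-retest reliability
        rmssd_scale = np.exp(cfg.subject_rmssd_sd * rng.normal())
        ibi_scale = np.exp(cfg.subject_ibi_sd * rng.normal())
        subj_cfg = replace(
            cfg,
            wake_rmssd_target=cfg.wake_rmssd_target * rmssd_scale,
            drowsy_rmssd_target=cfg.drowsy_rmssd_target * rmssd_scale,
            wake_ibi_mean=cfg.wake_ibi_mean * ibi_scale,
            drowsy_ibi_mean=cfg.drowsy_ibi_mean * ibi_scale,
        )
        c_subj = rng.uniform(*cfg.global_share_range)
        lam_subj = rng.uniform(*cfg.module_coupling_range)
        signature = base + cfg.subject_signature_strength * rng.normal(
            size=(cfg.n_rois, k)
        ) / np.sqrt(k)
        for ses in sessions:
            if cfg.duplicate_sessions and ses == "B":
                ref = (subj, "A")
                timelines[(subj, ses)] = timelines[ref].copy()
                beats[(subj, ses)] = BeatTimeSeries(
                    subject_id=subj, session_id=ses, beat_times=beats[ref].beat_times.copy()
                )
                roits[(subj, ses)] = ROITimeSeriesMatrix(
                    subject_id=subj,
                    session_id=ses,
                    values=roits[ref].values.copy(),
                    tr=cfg.tr,
                    roi_labels=roi_labels,
                )
                continue
            timeline = simulate_timeline(cfg, rng)
            timelines[(subj, ses)] = timeline
            beats[(subj, ses)] = simulate_ibi(subj_cfg, timeline, rng, subj, ses)
            roits[(subj, ses)] = ROITimeSeriesMatrix(
                subject_id=subj,
                session_id=ses,
                values=_roi_session(
                    cfg, modules, signature, sleep, c_subj, lam_subj, timeline, rng
                ),
                tr=cfg.tr,
                roi_labels=roi_labels,
            )
    return Cohort(
        tr=cfg.tr,
        n_volumes=cfg.n_volumes,
        subjects=subjects,
        sessions=sessions,
        beats=beats,
        roits=roits,
        timelines=timelines,
        partition=partition,
        config=cfg,
    )
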