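"""Interbeat-interval processing and time-varying heart-rate-variability metrics.

Beat times (seconds, relative to the onset of the first retained fMRI volume)
are converted to interbeat intervals (IBIs, ms), cleaned of ectopic values,
detrended, and summarised with RMSSD or the Toichi cardiac vagal index (CVI).
Sliding windows centred on the middle of each repetition time (TR) turn the
IBI series into one HRV value per fMRI volume, the per-volume sleepiness index
used by the censoring stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BeatTimeSeries",
    "IBISeries",
    "TimeVaryingHRV",
    "WindowSelectionReport",
    "beats_to_ibi",
    "clean_ibi",
    "rmssd",
    "cvi",
    "overall_hrv",
    "sliding_hrv",
    "consistency_ratio",
    "window_selection_report",
    "MIN_INTERVALS",
    "DEFAULT_WINDOW_CANDIDATES",
]

#: minimum number of intervals inside a window for the metric to be defined
MIN_INTERVALS = {"rmssd": 2, "cvi": 3}

#: candidate sliding-window lengths (s): 4, 8, ..., 48 plus 50
DEFAULT_WINDOW_CANDIDATES = tuple(float(w) for w in range(4, 49, 4)) + (50.0,)


@dataclass(frozen=True)
class BeatTimeSeries:
    """Detected heartbeat times for one subject-session.

    Beat detection itself (QRS identification from the raw ECG) is upstream;
    this type is its output.
    """

    subject_id: str
    session_id: str
    beat_times: np.ndarray  # seconds, strictly increasing

    def __post_init__(self) -> None:
        times = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", times)
        if times.size < 2:
            raise ValueError("insufficient beats")
        if not np.all(np.isfinite(times)):
            raise ValueError("non-finite beat times")
        if np.any(np.diff(times) <= 0):
            raise ValueError("non-monotonic beats")


@dataclass(frozen=True)
class IBISeries:
    """Interbeat intervals anchored in scan time.

    ``intervals`` are in milliseconds; ``anchor_times[i]`` is the time (s) of
    the terminating beat of interval ``i``.
    """

    intervals: np.ndarray
    anchor_times: np.ndarray
    cleaned: bool = False

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        at = np.asarray(self.anchor_times, dtype=float)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "anchor_times", at)
        if iv.shape != at.shape:
            raise ValueError("intervals and anchor_times must align")
        if iv.size and np.any(iv <= 0):
            raise ValueError("non-positive interval")
        if at.size > 1 and np.any(np.diff(at) <= 0):
            raise ValueError("anchor times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class TimeVaryingHRV:
    """One HRV value per fMRI volume; NaN marks volumes with too few intervals."""

    metric: str
    window_length: float  # seconds
    tr: float  # seconds
    values: np.ndarray  # length n_volumes, NaN = undefined
    n_volumes: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.size != self.n_volumes:
            raise ValueError("values must have one entry per volume")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of volumes with a defined HRV value."""
        return np.isfinite(self.values)


@dataclass
class WindowSelectionReport:
    """Diagnostics used to pick the sliding-window length.

    A window qualifies when its time-varying HRV is highly consistent with
    the whole-scan HRV (consistency ratio > ``consistency_min``); among the
    qualifying lengths the one with the highest scan-wise ICC wins, ties going
    to the shorter window.
    """

    candidate_lengths: tuple
    consistency_ratio: dict
    unit_wise_icc: dict
    scan_wise_icc: dict
    chosen_length: float | None = None
    consistency_min: float = 0.95
    warning: str | None = None


def beats_to_ibi(beats: BeatTimeSeries) -> IBISeries:
    """Difference successive beat times into interbeat intervals (ms)."""
    times = beats.beat_times
    intervals = np.diff(times) * 1000.0
    return IBISeries(intervals=intervals, anchor_times=times[1:], cleaned=False)


def _local_median(x: np.ndarray, width: int = 5) -> np.ndarray:
    """Centered running median, window truncated at the edges."""
    half = width // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def clean_ibi(ibi: IBISeries, ectopic_threshold: float = 0.20) -> IBISeries:
    """Remove ectopic intervals and apply a mean-preserving linear detrend.

    An interval is ectopic when it deviates from the local median (window of
    5) by more than ``ectopic_threshold`` as a fraction of that median.
    Ectopic values are replaced by linear interpolation between the nearest
    non-ectopic neighbours (in anchor time); a least-squares linear trend is
    then subtracted and the series mean re-added.
    """
    if len(ibi) == 0:
        raise ValueError("empty IBI series")
    x = ibi.intervals.copy()
    med = _local_median(x)
    ectopic = np.abs(x - med) > ectopic_threshold * med
    if np.all(ectopic):
        raise ValueError("series unusable")
    if np.any(ectopic):
        good = ~ectopic
        x[ectopic] = np.interp(
            ibi.anchor_times[ectopic], ibi.anchor_times[good], x[good]
        )
    # mean-preserving linear detrend against anchor time
    slope, intercept = np.polyfit(ibi.anchor_times, x, 1)
    trend = slope * ibi.anchor_times + intercept
    x = x - trend + x.mean()
    return IBISeries(intervals=x, anchor_times=ibi.anchor_times, cleaned=True)


def rmssd(intervals: Sequence[float]) -> float:
    """Root mean square of successive IBI differences (ms).

    Returns NaN when fewer than two intervals are available.
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < MIN_INTERVALS["rmssd"]:
        return float("nan")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def cvi(intervals: Sequence[float]) -> float:
    """Toichi cardiac vagal index from the Lorenz (Poincare) plot.

    With consecutive-interval pairs (x_n, x_{n+1}): SD1 is the sample SD of
    (x_{n+1} - x_n)/sqrt(2), SD2 of (x_{n+1} + x_n)/sqrt(2); the transverse
    and longitudinal axes are T = 4*SD1 and L = 4*SD2, and CVI = log10(L*T).
    Returns NaN when fewer than three intervals are given or either axis
    collapses (zero SD).
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < MIN_INTERVALS["cvi"]:
        return float("nan")
    diff = (x[1:] - x[:-1]) / np.sqrt(2.0)
    summ = (x[1:] + x[:-1]) / np.sqrt(2.0)
    sd1 = float(np.std(diff, ddof=1))
    sd2 = float(np.std(summ, ddof=1))
    if sd1 == 0.0 or sd2 == 0.0:
        return float("nan")
    return float(np.log10((4.0 * sd2) * (4.0 * sd1)))


_METRIC_FUNCS = {"rmssd": rmssd, "cvi": cvi}


def overall_hrv(ibi: IBISeries, metric: str = "rmssd") -> float:
    """Whole-scan HRV: the metric computed on the full IBI series."""
    return _METRIC_FUNCS[metric](ibi.intervals)


def sliding_hrv(
    ibi: IBISeries,
    metric: str,
    window_length: float,
    tr: float,
    n_volumes: int,
) -> TimeVaryingHRV:
    """Compute the chosen HRV metric in sliding windows aligned to volumes.

    The window for volume ``i`` is the half-open interval
    ``[(i + 0.5)*tr - W/2, (i + 0.5)*tr + W/2)``; an interval belongs to the
    window iff its anchor time (terminating beat) falls inside. Windows
    reaching beyond the recording are implicitly truncated to the available
    intervals; windows with fewer than the metric's minimum interval count
    yield NaN, never a silent zero.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if n_volumes < 1:
        raise ValueError("need at least one volume")
    func = _METRIC_FUNCS[metric]
    min_n = MIN_INTERVALS[metric]
    centers = (np.arange(n_volumes) + 0.5) * tr
    lo = centers - window_length / 2.0
    hi = centers + window_length / 2.0
    # half-open membership via searchsorted on the sorted anchor times
    start = np.searchsorted(ibi.anchor_times, lo, side="left")
    stop = np.searchsorted(ibi.anchor_times, hi, side="left")
    values = np.full(n_volumes, np.nan)
    for i in range(n_volumes):
        if stop[i] - start[i] >= min_n:
            values[i] = func(ibi.intervals[start[i] : stop[i]])
    return TimeVaryingHRV(
        metric=metric,
        window_length=float(window_length),
        tr=float(tr),
        values=values,
        n_volumes=int(n_volumes),
    )


def consistency_ratio(
    tv_collection: Sequence[TimeVaryingHRV], overall_collection: Sequence[float]
) -> float:
    """Ratio of mean windowed HRV to mean whole-scan HRV across subjects.

    The numerator averages every defined windowed value across windows and
    subjects; the denominator averages the whole-scan metric across subjects.
    """
    windowed = np.concatenate([tv.values for tv in tv_collection])
    windowed = windowed[np.isfinite(windowed)]
    overall = np.asarray(overall_collection, dtype=float)
    overall = overall[np.isfinite(overall)]
    if windowed.size == 0 or overall.size == 0:
        raise ValueError("no defined HRV values")
    denom = overall.mean()
    if denom == 0:
        raise ValueError("zero overall HRV")
    return float(windowed.mean() / denom)


def window_selection_report(
    candidates: Sequence[float],
    ibi_by_key: Mapping[tuple, IBISeries],
    tr: float,
    n_volumes: int,
    metric: str = "rmssd",
    consistency_min: float = 0.95,
) -> WindowSelectionReport:
    """Evaluate candidate window lengths on a two-session cohort.

    ``ibi_by_key`` maps ``(subject_id, session_id)`` to a cleaned IBI series;
    every subject must appear in exactly two sessions. For each candidate
    length the report carries the consistency ratio and the unit-/scan-wise
    ICC of the time-varying HRV, with windows as the measurement units
    (windows undefined for any subject-session are dropped from the table).
    """
    from .reliability import scan_wise_icc, unit_wise_icc

    candidates = tuple(float(c) for c in candidates)
    if not candidates:
        raise ValueError("no candidate window lengths")
    keys = sorted(ibi_by_key)
    subjects = sorted({k[0] for k in keys})
    sessions = sorted({k[1] for k in keys})
    if len(sessions) != 2 or any((s, ses) not in ibi_by_key for s in subjects for ses in sessions):
        raise ValueError("two sessions per subject required")

    overall = [overall_hrv(ibi_by_key[k], metric) for k in keys]
    ratios: dict = {}
    unit_icc: dict = {}
    scan_icc: dict = {}
    for w in candidates:
        tvs = {k: sliding_hrv(ibi_by_key[k], metric, w, tr, n_volumes) for k in keys}
        ratios[w] = consistency_ratio(list(tvs.values()), overall)
        # windows x subjects x sessions table, complete rows only
        cube = np.stack(
            [
                np.stack([tvs[(s, ses)].values for ses in sessions], axis=1)
                for s in subjects
            ],
            axis=1,
        )  # (n_volumes, n_subjects, 2)
        complete = np.isfinite(cube).all(axis=(1, 2))
        if complete.sum() >= 1:
            table = cube[complete]
            unit_icc[w] = unit_wise_icc(table).unit_wise
            scan_icc[w] = scan_wise_icc(table)
        else:
            unit_icc[w] = float("nan")
            scan_icc[w] = float("nan")

    qualifying = [
        w
        for w in candidates
        if ratios[w] > consistency_min and np.isfinite(scan_icc[w])
    ]
    report = WindowSelectionReport(
        candidate_lengths=candidates,
        consistency_ratio=ratios,
        unit_wise_icc=unit_icc,
        scan_wise_icc=scan_icc,
        consistency_min=consistency_min,
    )
    if qualifying:
        best = max(qualifying, key=lambda w: (scan_icc[w], -w))
        report.chosen_length = best
    else:
        report.warning = "no candidate window meets the consistency criterion"
    return report
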