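"""Plain-text readers and writers for every exchange format.

All formats are line-oriented text: beat times (one float per line), IBI and
tv-HRV tables (tab-separated), retention masks, ROI x volume time-series
tables (``sub-<ID>_ses-<ID>_roits.tsv``), square connectivity matrices with
ROI-label headers, network partitions, and SPM-dialect realignment parameter
files. ``#`` starts a comment everywhere.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .censoring import VolumeMask
from .connectivity import ConnectivityMatrix, ROITimeSeriesMatrix
from .hrv import BeatTimeSeries, IBISeries, TimeVaryingHRV
from .motion import RealignmentTrace
from .synthetic import Cohort, SimulationConfig

__all__ = [
    "read_beat_times",
    "write_beat_times",
    "read_ibi",
    "write_ibi",
    "read_tv_hrv",
    "write_tv_hrv",
    "read_mask",
    "write_mask",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_matrix",
    "write_matrix",
    "read_network_partition",
    "write_network_partition",
    "read_realignment",
    "read_simulation_config",
    "write_simulation_config",
    "write_cohort",
    "read_cohort",
]

_ROITS_PATTERN = re.compile(r"sub-(?P<sub>[^_]+)_ses-(?P<ses>[^_]+)_roits\.tsv$")


def _data_lines(path: Path) -> list[str]:
    lines = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            lines.append(stripped)
    return lines


def read_beat_times(path, subject_id: str = "", session_id: str = "") -> BeatTimeSeries:
    """One floating-point beat time (s) per line; '#' comments ignored."""
    times = np.array([float(x) for x in _data_lines(Path(path))])
    return BeatTimeSeries(subject_id=subject_id, session_id=session_id, beat_times=times)


def write_beat_times(path, beats: BeatTimeSeries) -> None:
    lines = [f"# beat times (s) sub-{beats.subject_id} ses-{beats.session_id}"]
    lines += [f"{t:.6f}" for t in beats.beat_times]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ibi(path) -> IBISeries:
    """Two tab-separated columns: anchor_time_s, interval_ms."""
    rows = [line.split("\t") for line in _data_lines(Path(path))]
    anchors = np.array([float(r[0]) for r in rows])
    intervals = np.array([float(r[1]) for r in rows])
    return IBISeries(intervals=intervals, anchor_times=anchors)


def write_ibi(path, ibi: IBISeries) -> None:
    lines = ["# anchor_time_s\tinterval_ms"]
    lines += [f"{t:.6f}\t{v:.6f}" for t, v in zip(ibi.anchor_times, ibi.intervals)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_tv_hrv(path, tv: TimeVaryingHRV) -> None:
    """Columns volume_index (0-based), time_s, value; empty value = undefined."""
    lines = [
        f"# metric={tv.metric} window_length_s={tv.window_length} tr_s={tv.tr}",
        "# volume_index\ttime_s\tvalue",
    ]
    for i, v in enumerate(tv.values):
        t = (i + 0.5) * tv.tr
        val = "" if not np.isfinite(v) else f"{v:.6f}"
        lines.append(f"{i}\t{t:.6f}\t{val}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tv_hrv(path) -> TimeVaryingHRV:
    header = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            for token in stripped.lstrip("# ").split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    header[k] = v
            continue
        if stripped:
            rows.append(stripped.split("\t"))
    values = np.array([float(r[2]) if len(r) > 2 and r[2] != "" else np.nan for r in rows])
    return TimeVaryingHRV(
        metric=header.get("metric", "rmssd"),
        window_length=float(header.get("window_length_s", 16.0)),
        tr=float(header.get("tr_s", 2.2)),
        values=values,
        n_volumes=values.size,
    )


def write_mask(path, mask: VolumeMask) -> None:
    """Columns volume_index, retained (0/1); header records mode/percentile/seed."""
    lines = [
        f"# mode={mask.mode} percentile={mask.percentile} seed={mask.seed}",
        "# volume_index\tretained",
    ]
    lines += [f"{i}\t{int(r)}" for i, r in enumerate(mask.retained)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mask(path) -> VolumeMask:
    header = {}
    retained = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            for token in stripped.lstrip("# ").split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    header[k] = v
            continue
        if stripped:
            retained.append(bool(int(stripped.split("\t")[1])))
    seed = header.get("seed", "None")
    return VolumeMask(
        mode=header.get("mode", "whole"),
        percentile=float(header.get("percentile", 1.0)),
        retained=np.array(retained, dtype=bool),
        seed=None if seed == "None" else int(seed),
    )


def write_roi_timeseries(path, ts: ROITimeSeriesMatrix) -> None:
    """First column roi_label, remaining columns one volume each, no header."""
    with Path(path).open("w") as fh:
        for label, row in zip(ts.roi_labels, ts.values):
            fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_roi_timeseries(path, tr: float, subject_id: str | None = None, session_id: str | None = None) -> ROITimeSeriesMatrix:
    """Read a ``sub-<ID>_ses-<ID>_roits.tsv`` table; IDs parsed from the name
    when not given explicitly."""
    path = Path(path)
    if subject_id is None or session_id is None:
        m = _ROITS_PATTERN.search(path.name)
        if m:
            subject_id = subject_id or m.group("sub")
            session_id = session_id or m.group("ses")
        else:
            subject_id = subject_id or ""
            session_id = session_id or ""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return ROITimeSeriesMatrix(
        subject_id=subject_id,
        session_id=session_id,
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        tr=tr,
        roi_labels=tuple(df.iloc[:, 0].astype(str)),
    )


def write_matrix(path, cm: ConnectivityMatrix) -> None:
    """Square matrix with a roi_label header row and column."""
    labels = list(cm.roi_labels) or [f"roi{i + 1:03d}" for i in range(cm.n_rois)]
    with Path(path).open("w") as fh:
        fh.write("roi_label\t" + "\t".join(labels) + "\n")
        for label, row in zip(labels, cm.values):
            fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_matrix(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float),
        n_samples=0,
        roi_labels=tuple(df.columns),
    )


def read_network_partition(path) -> dict[str, str]:
    """Two tab-separated columns: roi_label, network_name."""
    out = {}
    for line in _data_lines(Path(path)):
        label, net = line.split("\t")[:2]
        out[label] = net
    return out


def write_network_partition(path, partition: Mapping[str, str]) -> None:
    lines = ["# roi_label\tnetwork_name"]
    lines += [f"{k}\t{v}" for k, v in partition.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_realignment(path) -> RealignmentTrace:
    """Whitespace-delimited 6-column text, SPM rp_*.txt dialect."""
    params = np.loadtxt(path, comments="#", ndmin=2)
    return RealignmentTrace(params=params)


def write_simulation_config(path, cfg: SimulationConfig) -> None:
    """Flat ``key: value`` text echo of the simulation configuration."""
    lines = [f"{k}: {v}" for k, v in vars(cfg).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_simulation_config(path) -> SimulationConfig:
    kwargs: dict = {}
    bools = {"duplicate_sessions"}
    ints = {"n_subjects", "n_volumes", "n_rois", "n_latent", "n_modules", "seed"}
    for line in _data_lines(Path(path)):
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key in bools:
            kwargs[key] = value == "True"
        elif key in ints:
            kwargs[key] = int(value)
        elif value.startswith("("):
            kwargs[key] = tuple(float(x) for x in value.strip("()").split(","))
        else:
            kwargs[key] = float(value)
    return SimulationConfig(**kwargs)


def write_cohort(directory, cohort: Cohort) -> None:
    """Emit the complete fixture tree (beats, ROI tables, timelines, config)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if cohort.config is not None:
        write_simulation_config(directory / "config.txt", cohort.config)
    for (subj, ses) in cohort.keys:
        stem = f"sub-{subj}_ses-{ses}"
        write_beat_times(directory / f"{stem}_beats.txt", cohort.beats[(subj, ses)])
        write_roi_timeseries(directory / f"{stem}_roits.tsv", cohort.roits[(subj, ses)])
        timeline = cohort.timelines.get((subj, ses))
        if timeline is not None:
            lines = ["# volume_index\tdrowsy"]
            lines += [f"{i}\t{int(d)}" for i, d in enumerate(timeline)]
            (directory / f"{stem}_timeline.tsv").write_text("\n".join(lines) + "\n")


def read_cohort(directory, tr: float | None = None) -> Cohort:
    """Load a fixture tree written by :func:`write_cohort`.

    Subjects present in fewer than two sessions are excluded (incomplete
    participants cannot enter a test-retest table).
    """
    directory = Path(directory)
    config = None
    cfg_path = directory / "config.txt"
    if cfg_path.exists():
        config = read_simulation_config(cfg_path)
    if tr is None:
        tr = config.tr if config is not None else 2.2

    roits: dict = {}
    for path in sorted(directory.glob("sub-*_ses-*_roits.tsv")):
        ts = read_roi_timeseries(path, tr=tr)
        roits[(ts.subject_id, ts.session_id)] = ts
    beats: dict = {}
    for path in sorted(directory.glob("sub-*_ses-*_beats.txt")):
        m = re.search(r"sub-([^_]+)_ses-([^_]+)_beats\.txt$", path.name)
        beats[(m.group(1), m.group(2))] = read_beat_times(path, m.group(1), m.group(2))
    timelines: dict = {}
    for path in sorted(directory.glob("sub-*_ses-*_timeline.tsv")):
        m = re.search(r"sub-([^_]+)_ses-([^_]+)_timeline\.tsv$", path.name)
        vals = [bool(int(line.split("\t")[1])) for line in _data_lines(path)]
        timelines[(m.group(1), m.group(2))] = np.array(vals, dtype=bool)

    sessions = tuple(sorted({k[1] for k in roits}))
    complete = tuple(
        sorted(s for s in {k[0] for k in roits} if all((s, ses) in roits for ses in sessions))
    )
    dropped = sorted({k[0] for k in roits} - set(complete))
    if dropped:
        import warnings

        warnings.warn(f"excluding subjects with a missing session: {dropped}", UserWarning, stacklevel=2)
    keep = {k: v for k, v in roits.items() if k[0] in complete}
    n_volumes = next(iter(keep.values())).n_volumes if keep else 0
    return Cohort(
        tr=tr,
        n_volumes=n_volumes,
        subjects=complete,
        sessions=sessions,
        beats={k: v for k, v in beats.items() if k[0] in complete},
        roits=keep,
        timelines={k: v for k, v in timelines.items() if k[0] in complete},
        config=config,
    )
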