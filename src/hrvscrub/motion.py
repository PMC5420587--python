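"""Head-motion quality control: framewise displacement and spike frequency.

Framewise displacement (FD) summarises volume-to-volume head motion as the
sum of absolute backward differences of the six realignment parameters, with
rotations converted to arc length on a 50 mm sphere. A spike is a volume with
FD strictly greater than 0.3 mm; spike frequency (spikes per volume) is
compared between censoring conditions with a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RealignmentTrace",
    "FDSummary",
    "framewise_displacement",
    "spike_frequency",
    "compare_motion",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_SPIKE_THRESHOLD_MM = 0.3


@dataclass(frozen=True)
class RealignmentTrace:
    """Six rigid-body realignment parameters per volume.

    Columns: translations x, y, z (mm) then rotations pitch, yaw, roll.
    Rotations default to degrees (SPM emits radians; pass
    ``rotation_units="radians"`` to :func:`framewise_displacement`).
    """

    params: np.ndarray  # n_volumes x 6

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        object.__setattr__(self, "params", p)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError("expected an n_volumes x 6 parameter table")
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite realignment parameters")

    @property
    def n_volumes(self) -> int:
        return int(self.params.shape[0])


@dataclass(frozen=True)
class FDSummary:
    """Per-volume framewise displacement with the spike bookkeeping."""

    fd: np.ndarray  # mm, first volume 0
    spike_mask: np.ndarray
    spike_threshold: float
    spike_frequency: float


def framewise_displacement(
    trace: RealignmentTrace,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
    rotation_units: str = "degrees",
    spike_threshold: float = DEFAULT_SPIKE_THRESHOLD_MM,
) -> FDSummary:
    """Power-style framewise displacement from realignment parameters.

    FD_i = |dx_i| + |dy_i| + |dz_i| + r (|da_i| + |db_i| + |dg_i|) with
    backward differences (value_i - value_{i-1}), rotations in radians scaled
    by ``head_radius`` to millimetres of arc; FD_0 = 0.
    """
    if trace.n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if head_radius <= 0:
        raise ValueError("head_radius must be positive")
    p = trace.params.copy()
    if rotation_units == "degrees":
        p[:, 3:] = np.deg2rad(p[:, 3:])
    elif rotation_units != "radians":
        raise ValueError("rotation_units must be 'degrees' or 'radians'")
    delta = np.abs(np.diff(p, axis=0))
    fd = np.zeros(trace.n_volumes)
    fd[1:] = delta[:, :3].sum(axis=1) + head_radius * delta[:, 3:].sum(axis=1)
    spikes = fd > spike_threshold  # strictly greater
    return FDSummary(
        fd=fd,
        spike_mask=spikes,
        spike_threshold=float(spike_threshold),
        spike_frequency=float(spikes.mean()),
    )


def spike_frequency(fd: FDSummary, threshold: float = DEFAULT_SPIKE_THRESHOLD_MM) -> float:
    """Spikes per volume at an arbitrary threshold (strict >)."""
    return float(np.mean(fd.fd > threshold))


def compare_motion(
    freqs_a: Sequence[float], freqs_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject spike frequencies.

    Returns (t, p); with zero variance of the differences p is NaN unless the
    differences are identically zero, in which case (0, 1) — no evidence of a
    motion difference between conditions.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired values for >= 3 subjects")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0
    if np.allclose(diff, diff[0], rtol=0.0, atol=1e-12 * max(1.0, float(np.abs(diff).max()))):
        import warnings

        warnings.warn("zero variance of paired differences; p undefined", RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
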