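"""Volume-retention masks driven by per-volume HRV, and the alertness survival curve.

The censoring stage turns a time-varying HRV trace into a boolean retention
mask: keep the fraction ``percentile`` of volumes with the highest HRV
(``sleepy`` mode — HRV rises at the wake-to-sleep transition), the lowest
(``alert``), a uniform random subset (``random``, the volume-count control),
or everything (``whole``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hrv import TimeVaryingHRV

__all__ = [
    "VolumeMask",
    "SurvivalCurve",
    "select_volumes",
    "random_mask_ensemble",
    "alertness_survival",
]

MODES = ("sleepy", "alert", "random", "whole")


def _round_count(x: float) -> int:
    """Retained-count rounding: round-half-even, so that complementary
    percentiles never select overlapping sleepy/alert sets at odd n."""
    return int(np.rint(x))


@dataclass(frozen=True)
class VolumeMask:
    """Boolean per-volume retention mask for one censoring condition."""

    mode: str
    percentile: float
    retained: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "retained", np.asarray(self.retained, dtype=bool))
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.percentile <= 1.0):
            raise ValueError("percentile must be in (0, 1]")

    @property
    def n_volumes(self) -> int:
        return int(self.retained.size)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)


@dataclass(frozen=True)
class SurvivalCurve:
    """Number of subjects still continuously alert at each volume.

    A subject drops out at the volume that completes a run of
    ``dropout_run`` consecutive sleepy volumes and stays dropped thereafter.
    """

    threshold: float
    counts: np.ndarray
    dropout_run: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))


def select_volumes(
    tv: TimeVaryingHRV,
    mode: str,
    percentile: float,
    seed: int | None = None,
) -> VolumeMask:
    """Build a retention mask at retention fraction ``percentile``.

    In ``sleepy``/``alert`` modes the retained count is
    round(percentile * n_defined) over volumes with defined HRV; volumes with
    undefined HRV are never selected. Ties are broken toward the earlier
    volume index. ``random`` mode samples round(percentile * n_total) volumes
    uniformly without replacement from *all* volumes using ``seed``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not (0.0 < percentile <= 1.0):
        raise ValueError("percentile must be in (0, 1]")
    n = tv.n_volumes
    retained = np.zeros(n, dtype=bool)

    if mode == "whole":
        retained[:] = True
        return VolumeMask(mode=mode, percentile=1.0, retained=retained)

    if mode == "random":
        rng = np.random.default_rng(seed)
        k = _round_count(percentile * n)
        idx = rng.choice(n, size=k, replace=False)
        retained[idx] = True
        return VolumeMask(mode=mode, percentile=percentile, retained=retained, seed=seed)

    defined_idx = np.flatnonzero(tv.defined)
    if defined_idx.size == 0:
        raise ValueError("no defined HRV values to rank")
    k = _round_count(percentile * defined_idx.size)
    vals = tv.values[defined_idx]
    if mode == "sleepy":
        # lexsort: primary key last; stable earlier-index tie-break
        order = np.lexsort((defined_idx, -vals))
    else:  # alert
        order = np.lexsort((defined_idx, vals))
    retained[defined_idx[order[:k]]] = True
    return VolumeMask(mode=mode, percentile=percentile, retained=retained)


def random_mask_ensemble(
    n_volumes: int,
    percentile: float,
    n_draws: int = 5000,
    seed: int | None = None,
) -> list[VolumeMask]:
    """Draw ``n_draws`` independent random retention masks, reproducibly.

    The ensemble is the empirical null for the permutation test: the same
    retained-volume count as the HRV-based conditions, with no relation to
    sleepiness.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not (0.0 < percentile <= 1.0):
        raise ValueError("percentile must be in (0, 1]")
    rng = np.random.default_rng(seed)
    k = _round_count(percentile * n_volumes)
    masks = []
    for _ in range(n_draws):
        retained = np.zeros(n_volumes, dtype=bool)
        retained[rng.choice(n_volumes, size=k, replace=False)] = True
        masks.append(
            VolumeMask(mode="random", percentile=percentile, retained=retained, seed=seed)
        )
    return masks


def alertness_survival(
    sleepy_masks: Sequence[VolumeMask],
    dropout_run: int = 5,
    threshold: float = 0.5,
) -> SurvivalCurve:
    """Count subjects who have stayed continuously alert up to each volume.

    ``sleepy_masks`` holds one sleepy-condition mask per subject (retained =
    sleepy volume). A subject drops out at the first volume ending
    ``dropout_run`` consecutive sleepy volumes.
    """
    if dropout_run < 1:
        raise ValueError("dropout_run must be >= 1")
    n_volumes = sleepy_masks[0].n_volumes
    if any(m.n_volumes != n_volumes for m in sleepy_masks):
        raise ValueError("masks must share n_volumes")
    counts = np.full(n_volumes, len(sleepy_masks), dtype=int)
    for mask in sleepy_masks:
        run = 0
        for v, sleepy in enumerate(mask.retained):
            run = run + 1 if sleepy else 0
            if run >= dropout_run:
                counts[v:] -= 1
                break
    return SurvivalCurve(threshold=threshold, counts=counts, dropout_run=dropout_run)
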