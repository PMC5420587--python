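"""Test-retest reliability: one-way ICC, unit-/scan-wise summaries, permutation test.

The intraclass correlation coefficient here is the one-way random-effects
form: a one-way ANOVA across subjects on the d sessions per subject gives the
between-subject mean square MS_b and within-subject mean square MS_w, and

    ICC = (MS_b - MS_w) / (MS_b + (d - 1) MS_w).

Unit-wise reliability computes one ICC per measurement unit (edge, node or
HRV window) and averages over units; scan-wise reliability collapses the
units to their per-scan mean first and computes a single ICC. Significance
against random volume selection comes from a one-tailed permutation test on
the ICC distribution of random-censoring draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ICCResult",
    "PermutationNull",
    "icc",
    "icc_array",
    "unit_wise_icc",
    "scan_wise_icc",
    "icc_band",
    "permutation_test",
]

#: qualitative reliability bands, half-open, boundary assigned upward
_BANDS = (
    (0.8, "excellent"),
    (0.6, "good"),
    (0.4, "moderate"),
    (0.2, "fair"),
    (-np.inf, "poor"),
)


def icc_array(x: np.ndarray) -> np.ndarray:
    """Vectorised one-way ICC over the trailing (subjects, sessions) axes.

    ``x`` has shape (..., n_subjects, d). Degenerate cells (all values
    identical, zero total variance) come back NaN. Negative ICCs are returned
    as-is, never floored — flooring would bias the permutation null.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape[-2], x.shape[-1]
    if n < 2 or d < 2:
        raise ValueError("need >= 2 subjects and >= 2 sessions")
    subj_means = x.mean(axis=-1)
    grand = subj_means.mean(axis=-1, keepdims=True)
    ms_b = d * ((subj_means - grand) ** 2).sum(axis=-1) / (n - 1)
    ms_w = ((x - subj_means[..., None]) ** 2).sum(axis=(-2, -1)) / (n * (d - 1))
    denom = ms_b + (d - 1) * ms_w
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ms_b - ms_w) / denom
    return np.where(denom > 0, out, np.nan)


def icc(values: np.ndarray) -> float:
    """One-way ICC of a complete subjects x sessions table."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a subjects x sessions table")
    if not np.all(np.isfinite(values)):
        raise ValueError("table must be complete")
    return float(icc_array(values))


@dataclass(frozen=True)
class ICCResult:
    """Per-unit ICCs with their unit-wise mean and bands."""

    per_unit_icc: np.ndarray
    unit_wise: float
    d: int
    n_undefined: int

    @property
    def bands(self) -> list[str]:
        return [icc_band(v) for v in self.per_unit_icc]


def unit_wise_icc(table: np.ndarray) -> ICCResult:
    """ICC per measurement unit, averaged over units with a defined value.

    ``table`` has shape (n_units, n_subjects, d) and must be complete;
    units whose ICC is undefined (zero total variance) are counted and
    excluded from the average.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 3:
        raise ValueError("expected a units x subjects x sessions array")
    per_unit = icc_array(table)
    defined = np.isfinite(per_unit)
    if not np.any(defined):
        raise ValueError("all units undefined")
    return ICCResult(
        per_unit_icc=per_unit,
        unit_wise=float(per_unit[defined].mean()),
        d=int(table.shape[-1]),
        n_undefined=int(np.sum(~defined)),
    )


def scan_wise_icc(table: np.ndarray) -> float:
    """ICC of the per-scan mean measurement.

    Units are collapsed by their mean within each subject-session; the single
    ICC of the resulting subjects x sessions table estimates the reliability
    of the scan-level summary measure.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 3:
        raise ValueError("expected a units x subjects x sessions array")
    return float(icc_array(table.mean(axis=0)))


def icc_band(value: float) -> str:
    """Qualitative reliability label; gaps in the printed bands are closed
    with half-open intervals, boundaries assigned to the higher band."""
    if not np.isfinite(value):
        return "undefined"
    for lo, label in _BANDS:
        if value >= lo:
            return label
    return "poor"  # pragma: no cover


@dataclass(frozen=True)
class PermutationNull:
    """One-tailed permutation test of an observed ICC against a random null."""

    observed: float
    null_iccs: np.ndarray
    tail: str
    p_value: float
    lower_bound: float  # empirical 5th percentile of the null
    upper_bound: float  # empirical 95th percentile
    null_mean: float

    @property
    def n(self) -> int:
        return int(self.null_iccs.size)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def permutation_test(
    observed: float,
    null: Sequence[float],
    tail: str = "right",
) -> PermutationNull:
    """Compare an observed ICC to the random-censoring null distribution.

    The p-value uses the add-one estimator, p = (1 + #{null >= observed}) /
    (1 + N) for the right tail (symmetrically for the left), so p is never 0.
    Bounds are the linear-interpolation 5th/95th percentiles of the null.
    N >= 19 is required: the smallest attainable p is 1/(1 + N), so 19 draws
    are the minimum at which alpha = 0.05 is reachable at all.
    """
    null_arr = np.asarray(null, dtype=float)
    null_arr = null_arr[np.isfinite(null_arr)]
    if null_arr.size < 19:
        raise ValueError("null too small for alpha 0.05")
    if tail == "right":
        count = int(np.sum(null_arr >= observed))
    elif tail == "left":
        count = int(np.sum(null_arr <= observed))
    else:
        raise ValueError("tail must be 'right' or 'left'")
    p = (1 + count) / (1 + null_arr.size)
    lo, hi = np.percentile(null_arr, [5.0, 95.0])
    return PermutationNull(
        observed=float(observed),
        null_iccs=null_arr,
        tail=tail,
        p_value=float(p),
        lower_bound=float(lo),
        upper_bound=float(hi),
        null_mean=float(null_arr.mean()),
    )
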