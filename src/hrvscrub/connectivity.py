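"""ROI-pairwise functional connectivity from retained volumes.

Pearson correlation matrices over the volumes a mask retains, Fisher
z-transformation for variance-stabilised group averaging, and edgewise paired
contrasts between censoring conditions with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .censoring import VolumeMask

__all__ = [
    "ROITimeSeriesMatrix",
    "ConnectivityMatrix",
    "PairedContrast",
    "fc_matrix",
    "fisher_z",
    "inverse_fisher",
    "group_average_fc",
    "paired_contrast",
]

# collinearity clip applied to off-diagonal entries before arctanh
_R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ROITimeSeriesMatrix:
    """Preprocessed mean BOLD signal per ROI per volume (one subject-session)."""

    subject_id: str
    session_id: str
    values: np.ndarray  # n_rois x n_volumes
    tr: float
    roi_labels: tuple

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        if vals.ndim != 2 or vals.shape[0] < 2 or vals.shape[1] < 3:
            raise ValueError("need an n_rois x n_volumes matrix, >=2 ROIs, >=3 volumes")
        if len(self.roi_labels) != vals.shape[0]:
            raise ValueError("one label per ROI required")
        if not np.all(np.isfinite(vals)):
            raise ValueError("missing values in ROI time series")

    @property
    def n_rois(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_volumes(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson-r matrix; NaN rows flag zero-variance ROIs."""

    values: np.ndarray
    n_samples: int
    roi_labels: tuple = ()
    mask_mode: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("connectivity matrix must be square")

    @property
    def n_rois(self) -> int:
        return int(self.values.shape[0])

    @property
    def undefined_rois(self) -> np.ndarray:
        """Indices of ROIs whose correlations are undefined (zero variance)."""
        off = self.values.copy()
        np.fill_diagonal(off, 0.0)
        return np.flatnonzero(np.all(~np.isfinite(off) | (off == 0), axis=1) & np.any(~np.isfinite(off), axis=1))


def fc_matrix(ts: ROITimeSeriesMatrix, mask: VolumeMask) -> ConnectivityMatrix:
    """Pearson correlation between every ROI pair over retained volumes only.

    The retained volumes are used as one concatenated (non-contiguous) sample.
    A ROI with zero variance over the retained volumes yields NaN correlations
    (flagged with a warning), never silent zeros; the diagonal is forced to 1.
    """
    if mask.n_volumes != ts.n_volumes:
        raise ValueError("mask length must equal n_volumes")
    kept = ts.values[:, mask.retained]
    if kept.shape[1] < 3:
        raise ValueError("fewer than 3 retained volumes")
    sd = kept.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(kept)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} ROI(s) with zero variance over retained volumes; "
            "their correlations are undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        values=r,
        n_samples=int(kept.shape[1]),
        roi_labels=ts.roi_labels,
        mask_mode=mask.mode,
    )


def fisher_z(r, clip: bool = False):
    """Fisher z-transform, ``arctanh(r)``.

    With ``clip=False`` (scalar contract) an input of exactly +-1 raises; with
    ``clip=True`` off-limit values are clipped to +-(1 - 1e-7) with a warning,
    the policy used for whole matrices where tiny fixtures can be collinear.
    """
    arr = np.asarray(r, dtype=float)
    if clip:
        if np.any(np.abs(arr) >= 1.0):
            warnings.warn("|r| >= 1 clipped before Fisher transform", RuntimeWarning, stacklevel=2)
            arr = np.clip(arr, -_R_CLIP, _R_CLIP)
    elif np.any(np.abs(arr) >= 1.0):
        raise ValueError("transform diverges")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def inverse_fisher(z):
    """Inverse Fisher transform, ``tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


def _z_matrix(cm: ConnectivityMatrix) -> np.ndarray:
    """Fisher-z of a connectivity matrix with the off-diagonal clip policy."""
    r = cm.values.copy()
    np.fill_diagonal(r, 0.0)  # diagonal handled separately; arctanh(1) diverges
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) >= 1.0):
        warnings.warn("off-diagonal |r| >= 1 clipped before Fisher transform", RuntimeWarning, stacklevel=2)
        r[finite] = np.clip(r[finite], -_R_CLIP, _R_CLIP)
    with np.errstate(invalid="ignore"):
        return np.arctanh(r)


def group_average_fc(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Average connectivity matrices in Fisher-z space, revert to Pearson r."""
    if not matrices:
        raise ValueError("no matrices to average")
    shape = matrices[0].values.shape
    if any(m.values.shape != shape for m in matrices):
        raise ValueError("matrix shapes differ")
    z = np.mean([_z_matrix(m) for m in matrices], axis=0)
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        values=r,
        n_samples=int(np.mean([m.n_samples for m in matrices])),
        roi_labels=matrices[0].roi_labels,
        mask_mode=matrices[0].mask_mode,
    )


@dataclass(frozen=True)
class PairedContrast:
    """Edgewise paired-t contrast between two censoring conditions."""

    t: np.ndarray  # n_rois x n_rois, NaN on diagonal/undefined edges
    p: np.ndarray
    significant: np.ndarray  # boolean, FDR-corrected
    q: float
    n_undefined_edges: int


def paired_contrast(
    matrices_a: Sequence[ConnectivityMatrix],
    matrices_b: Sequence[ConnectivityMatrix],
    q: float = 0.05,
) -> PairedContrast:
    """Paired t-test on Fisher-z connectivity, edge by edge, with BH-FDR.

    The FDR family is the set of unique upper-triangle edges. Edges with zero
    within-pair variance (or undefined correlations) are excluded from the
    family with a warning.
    """
    if len(matrices_a) != len(matrices_b) or len(matrices_a) < 3:
        raise ValueError("need the same >=3 subjects in both conditions")
    za = np.stack([_z_matrix(m) for m in matrices_a])  # subjects x n x n
    zb = np.stack([_z_matrix(m) for m in matrices_b])
    n = za.shape[1]
    iu = np.triu_indices(n, k=1)
    da = za[:, iu[0], iu[1]]
    db = zb[:, iu[0], iu[1]]
    diff = da - db

    t_edges = np.full(diff.shape[1], np.nan)
    p_edges = np.full(diff.shape[1], np.nan)
    valid = np.isfinite(diff).all(axis=0) & (diff.std(axis=0) > 0)
    zero_diff = np.isfinite(diff).all(axis=0) & (diff.std(axis=0) == 0) & (np.abs(diff.mean(axis=0)) == 0)
    # identical conditions on an edge: t = 0, p = 1 (well-defined null result)
    t_edges[zero_diff] = 0.0
    p_edges[zero_diff] = 1.0
    if np.any(valid):
        res = stats.ttest_rel(da[:, valid], db[:, valid], axis=0)
        t_edges[valid] = res.statistic
        p_edges[valid] = res.pvalue
    in_family = valid | zero_diff
    n_undef = int(np.sum(~in_family))
    if n_undef:
        warnings.warn(
            f"{n_undef} edge(s) with undefined paired differences excluded from the FDR family",
            RuntimeWarning,
            stacklevel=2,
        )
    sig_edges = np.zeros(diff.shape[1], dtype=bool)
    if np.any(in_family):
        sig_edges[in_family] = multipletests(p_edges[in_family], alpha=q, method="fdr_bh")[0]

    t_mat = np.full((n, n), np.nan)
    p_mat = np.full((n, n), np.nan)
    s_mat = np.zeros((n, n), dtype=bool)
    t_mat[iu] = t_edges
    p_mat[iu] = p_edges
    s_mat[iu] = sig_edges
    t_mat[(iu[1], iu[0])] = t_edges
    p_mat[(iu[1], iu[0])] = p_edges
    s_mat[(iu[1], iu[0])] = sig_edges
    return PairedContrast(t=t_mat, p=p_mat, significant=s_mat, q=q, n_undefined_edges=n_undef)
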