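"""Weighted graph metrics on thresholded connectivity matrices.

A connectivity matrix is thresholded into a weighted adjacency matrix
(suprathreshold correlations keep their value as edge weight, the rest drop to
zero), from which node-level degree centrality and the weighted (Onnela)
clustering coefficient are computed, with optional aggregation into named
networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "AdjacencyMatrix",
    "NodeMetricVector",
    "threshold_matrix",
    "degree_centrality",
    "clustering_coefficient",
    "network_aggregate",
]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric nonnegative weighted adjacency with zero diagonal."""

    weights: np.ndarray
    threshold: float
    roi_labels: tuple = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(w, w.T, equal_nan=True):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return int(self.weights.shape[0])


@dataclass(frozen=True)
class NodeMetricVector:
    """One metric value per node at a given threshold."""

    metric: str
    values: np.ndarray
    threshold: float
    roi_labels: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))


def threshold_matrix(fc: ConnectivityMatrix, t_r: float) -> AdjacencyMatrix:
    """Keep correlations >= ``t_r`` as edge weights, zero the rest.

    The boundary is inclusive (an edge at exactly ``t_r`` is retained);
    negative correlations are always removed since ``t_r > 0``. NaN entries
    (undefined correlations) drop to zero weight.
    """
    if t_r <= 0:
        raise ValueError("t_r must be positive")
    r = fc.values.copy()
    with np.errstate(invalid="ignore"):
        w = np.where(np.isfinite(r) & (r >= t_r), r, 0.0)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0  # guard symmetry against asymmetric NaN patterns
    return AdjacencyMatrix(weights=w, threshold=float(t_r), roi_labels=fc.roi_labels)


def degree_centrality(adj: AdjacencyMatrix) -> NodeMetricVector:
    """Weighted degree: the sum of edge weights incident to each node."""
    return NodeMetricVector(
        metric="degree_centrality",
        values=adj.weights.sum(axis=1),
        threshold=adj.threshold,
        roi_labels=adj.roi_labels,
    )


def clustering_coefficient(adj: AdjacencyMatrix, kind: str = "weighted") -> NodeMetricVector:
    """Node-level clustering coefficient.

    ``weighted`` (default) is the Onnela form used by the Brain Connectivity
    Toolbox for weighted undirected matrices: with weights normalised by the
    matrix maximum, C_i = 2 t_i / (k_i (k_i - 1)) where t_i is the sum of
    geometric-mean triangle intensities (w_ij w_ih w_jh)^(1/3) / 2 around i
    and k_i the *binary* degree; C_i = 0 when k_i < 2. ``binary`` reduces to
    the classic fraction of realised triangles among neighbours.
    """
    w = adj.weights
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    if kind == "weighted":
        wmax = w.max()
        w_hat = w / wmax if wmax > 0 else w
        cr = np.cbrt(w_hat)
        # t_i = 1/2 * sum_{j,h} cr_ij cr_ih cr_jh = diag(cr^3)/2
        t = np.diag(cr @ cr @ cr) / 2.0
    elif kind == "binary":
        t = np.diag(a @ a @ a) / 2.0
    else:
        raise ValueError(f"unknown clustering kind {kind!r}")
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return NodeMetricVector(
        metric="clustering_coefficient",
        values=c,
        threshold=adj.threshold,
        roi_labels=adj.roi_labels,
    )


def network_aggregate(
    nodes: NodeMetricVector | Sequence[float],
    partition: Mapping[str, str] | Sequence[str],
    stat: str = "mean",
) -> dict[str, float]:
    """Aggregate node-level values (metrics or node ICCs) into networks.

    ``partition`` maps every node to a network label (e.g. the 7-network
    scheme plus "other"); given as a mapping it is keyed by ROI label, given
    as a sequence it is positional. Empty networks never arise (every label in
    the partition has at least its own node).
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    if isinstance(nodes, NodeMetricVector):
        values = nodes.values
        labels = nodes.roi_labels
    else:
        values = np.asarray(nodes, dtype=float)
        labels = None
    if isinstance(partition, Mapping):
        if labels is None or not labels:
            raise ValueError("mapping partition requires labelled nodes")
        missing = [lab for lab in labels if lab not in partition]
        if missing:
            raise ValueError(f"unlabelled nodes: {missing[:5]}")
        nets = [partition[lab] for lab in labels]
    else:
        nets = list(partition)
        if len(nets) != values.size:
            raise ValueError("one network label per node required")
    series = pd.Series(values).groupby(pd.Series(nets))
    agg = series.mean() if stat == "mean" else series.median()
    return {str(k): float(v) for k, v in agg.items()}
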