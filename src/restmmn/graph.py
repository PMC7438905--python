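"""Binary graph construction and the two network measures.

The weighted coherence matrix w is binarized at threshold T (edge iff
w_ij >= T, no self-edges). On the binary graph with node set Omega of size
N the measures are:

    degree            k_i = sum_j a_ij
    triangles         t_i = 1/2 sum_{j,h} a_ij a_ih a_jh
    clustering        C   = 1/N sum_i 2 t_i / (k_i (k_i - 1))
    path length       L   = 1/N sum_i L_i,   L_i = sum_{j != i} d_ij / (N - 1)

with d_ij the shortest hop distance (breadth-first search). The local
clustering term is defined as 0 when k_i <= 1. Thresholded empirical
networks can disconnect even though the analysis assumes a connected graph;
the default "connected-pairs" policy excludes infinite distances and
divides by the number of reachable partners (with a logged warning), while
the "strict" policy raises instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .datatypes import BAND_ORDER, ValidationError
from .connectivity import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryNetwork",
    "NetworkMetrics",
    "DEFAULT_THRESHOLD",
    "binarize",
    "degree",
    "triangle_count",
    "clustering_coefficient",
    "shortest_paths",
    "characteristic_path_length",
    "network_metrics",
    "metrics_per_subject",
]

DEFAULT_THRESHOLD = 0.200


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    threshold: float
    nodes: tuple

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        if not (a == a.T).all():
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero (no self-edges)")
        object.__setattr__(self, "adjacency", a.astype(np.int64))
        object.__setattr__(self, "nodes", tuple(self.nodes))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def node_index(self, node) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise ValidationError(f"unknown node {node!r}") from None


@dataclass(frozen=True)
class NetworkMetrics:
    """Per-graph summary: C, L, and the per-node quantities behind them."""

    C: float
    L: float
    degrees: np.ndarray
    triangles: np.ndarray
    node_path_lengths: np.ndarray
    distances: np.ndarray
    connected: bool
    threshold: float


def binarize(w: "WeightedNetwork | np.ndarray", threshold: float = DEFAULT_THRESHOLD,
             nodes: Sequence = ()) -> BinaryNetwork:
    """Threshold a weighted matrix: edge iff w_ij >= T (ties included), i != j."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    if isinstance(w, WeightedNetwork):
        mat, node_list = w.w, w.nodes
    else:
        mat = np.asarray(w, dtype=float)
        node_list = tuple(nodes) if len(tuple(nodes)) else tuple(range(mat.shape[0]))
    a = (mat >= threshold).astype(np.int64)
    np.fill_diagonal(a, 0)
    return BinaryNetwork(adjacency=a, threshold=threshold, nodes=node_list)


def degree(net: BinaryNetwork, node) -> int:
    """Node degree k_i = sum_j a_ij."""
    return int(net.adjacency[net.node_index(node)].sum())


def triangle_count(net: BinaryNetwork, node) -> int:
    """t_i: triangles through node i, i.e. connected neighbour pairs."""
    i = net.node_index(node)
    a = net.adjacency
    nbrs = np.flatnonzero(a[i])
    return int(a[np.ix_(nbrs, nbrs)].sum() // 2)


def _degrees(a: np.ndarray) -> np.ndarray:
    return a.sum(axis=1)


def _triangles(a: np.ndarray) -> np.ndarray:
    return np.diag(a @ a @ a) // 2


def clustering_coefficient(net: BinaryNetwork) -> float:
    """Mean local clustering; the k_i <= 1 term is defined as 0."""
    a = net.adjacency
    if a.shape[0] == 0:
        raise ValidationError("empty graph")
    k = _degrees(a)
    t = _triangles(a)
    local = np.zeros(len(k), dtype=float)
    ok = k > 1
    local[ok] = 2.0 * t[ok] / (k[ok] * (k[ok] - 1.0))
    return float(local.mean())


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs hop distances by breadth-first search; inf if unreachable."""
    a = net.adjacency.astype(bool)
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    hop = 0
    while frontier.any():
        hop += 1
        nxt = (frontier @ a) & ~reached
        d[nxt] = hop
        reached |= nxt
        frontier = nxt
    return d


def characteristic_path_length(
    net: BinaryNetwork, disconnected_policy: str = "connected-pairs"
) -> float:
    """L = mean over nodes of mean shortest distance to the other nodes.

    Under ``"connected-pairs"`` infinite distances are excluded and each
    L_i divides by that node's count of reachable partners (nodes with no
    reachable partner are excluded from the outer mean); under ``"strict"``
    any unreachable pair raises.
    """
    if net.n_nodes < 2:
        raise ValidationError("path length needs at least 2 nodes")
    d = shortest_paths(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    if disconnected_policy == "strict":
        if not finite.sum() == off.sum():
            bad = net.nodes[int(np.argmin(finite.sum(axis=1)))]
            raise ValidationError(
                f"graph is disconnected (e.g. around node {bad!r}) under "
                "the 'strict' policy"
            )
        return float((d[off] / (net.n_nodes - 1)).sum() / net.n_nodes)
    if disconnected_policy != "connected-pairs":
        raise ValidationError(
            f"unknown disconnected_policy {disconnected_policy!r}"
        )
    if finite.sum() < off.sum():
        logger.warning(
            "graph disconnected at T=%.3f: averaging over connected pairs only",
            net.threshold,
        )
    counts = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        L_i = np.where(counts > 0, np.where(finite, d, 0.0).sum(axis=1) / np.maximum(counts, 1), np.nan)
    valid = counts > 0
    if not valid.any():
        logger.warning("graph has no edges; characteristic path length undefined")
        return float("nan")
    return float(L_i[valid].mean())


def network_metrics(
    net: BinaryNetwork, disconnected_policy: str = "connected-pairs"
) -> NetworkMetrics:
    """Compute C, L and the per-node quantities for one binary graph."""
    a = net.adjacency
    d = shortest_paths(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    connected = bool(np.isfinite(d[off]).all()) if net.n_nodes > 1 else True
    counts = (np.isfinite(d) & off).sum(axis=1)
    L_i = np.where(
        counts > 0, np.where(np.isfinite(d) & off, d, 0.0).sum(axis=1) / np.maximum(counts, 1), np.nan
    )
    return NetworkMetrics(
        C=clustering_coefficient(net),
        L=characteristic_path_length(net, disconnected_policy),
        degrees=_degrees(a),
        triangles=_triangles(a),
        node_path_lengths=L_i,
        distances=d,
        connected=connected,
        threshold=net.threshold,
    )


def metrics_per_subject(
    weighted_by_band: Dict[str, WeightedNetwork],
    threshold: float = DEFAULT_THRESHOLD,
    disconnected_policy: str = "connected-pairs",
    bands: "Sequence[str] | None" = None,
) -> pd.DataFrame:
    """One (C, L) row per band for one subject's weighted matrices.

    By default all five canonical bands must be present; pass ``bands`` to
    analyze a subset.
    """
    rows = []
    for band in (bands if bands is not None else BAND_ORDER):
        if band not in weighted_by_band:
            raise ValidationError(f"missing weighted matrix for band {band!r}")
        net = binarize(weighted_by_band[band], threshold)
        m = network_metrics(net, disconnected_policy)
        rows.append(
            {
                "band": band,
                "C": m.C,
                "L": m.L,
                "connected": m.connected,
                "threshold": threshold,
            }
        )
    return pd.DataFrame(rows)
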