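"""Downstream characterization of reconstructed interaction networks.

Thresholds the decoded probability matrix to the top fraction of
high-confidence edges (5% by default), compares intra- versus inter-cluster
edge length distributions with a two-sample Kolmogorov-Smirnov test,
computes degree / closeness centrality, and calls hub cells (degree > 10 by
default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.stats import ks_2samp


@dataclass
class InteractionNetwork:
    """Scored undirected edge list over cells with optional metadata."""

    edges: np.ndarray          # (E, 2) int, i < j, unique
    scores: np.ndarray         # (E,) float
    n_cells: int
    coords: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.scores):
            raise ValueError("edges and scores length mismatch")
        if len(self.edges):
            if np.any(self.edges[:, 0] >= self.edges[:, 1]):
                raise ValueError("edges must satisfy i < j")
            keys = {tuple(e) for e in self.edges.tolist()}
            if len(keys) != len(self.edges):
                raise ValueError("duplicate edges")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def threshold_top_edges(
    A_hat: np.ndarray,
    fraction: float = 0.05,
    coords: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> InteractionNetwork:
    """Retain the top ``ceil(fraction * P)`` unique off-diagonal pairs.

    Ties break deterministically by (i, j) order.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = A_hat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    scores = A_hat[iu, ju]
    n_keep = math.ceil(fraction * len(scores))
    order = np.lexsort((ju, iu, -scores))[:n_keep]
    order = order[np.argsort(-scores[order], kind="stable")]
    return InteractionNetwork(
        edges=np.c_[iu[order], ju[order]],
        scores=scores[order],
        n_cells=n,
        coords=coords,
        labels=labels,
    )


def intra_inter_distance_test(
    net: InteractionNetwork, labels: list[str] | None = None
):
    """KS test of intra- vs inter-cluster interacting pair distances.

    Returns (statistic, p-value, intra distances, inter distances). The
    statistic is the supremum ECDF difference; the p-value is the
    asymptotic two-sample approximation.
    """
    labels = labels if labels is not None else net.labels
    if labels is None or net.coords is None:
        raise ValueError("labels and coordinates required")
    labels = np.asarray(labels)
    d = np.linalg.norm(
        net.coords[net.edges[:, 0]] - net.coords[net.edges[:, 1]], axis=1
    )
    same = labels[net.edges[:, 0]] == labels[net.edges[:, 1]]
    intra, inter = d[same], d[~same]
    if len(intra) == 0:
        raise ValueError("no intra-cluster edges")
    if len(inter) == 0:
        raise ValueError("no inter-cluster edges")
    res = ks_2samp(intra, inter, method="asymp")
    return float(res.statistic), float(res.pvalue), intra, inter


def topology_stats(net: InteractionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-node degree and component-normalized closeness centrality.

    Closeness of node v is ``(n_reach - 1) / sum of shortest-path lengths``
    to the nodes reachable from v; isolated nodes get 0.
    """
    n = net.n_cells
    if len(net.edges) == 0:
        raise ValueError("empty network")
    A = sparse.csr_matrix(
        (np.ones(len(net.edges)), (net.edges[:, 0], net.edges[:, 1])), shape=(n, n)
    )
    A = A + A.T
    degree = np.asarray((A > 0).sum(axis=1)).ravel()
    sp = shortest_path(A > 0, method="D", unweighted=True)
    closeness = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(sp[v]) & (np.arange(n) != v)
        nr = int(reach.sum())
        if nr > 0:
            closeness[v] = nr / sp[v, reach].sum()
    return degree, closeness


def find_hubs(net: InteractionNetwork, degree_threshold: int = 10) -> set[int]:
    """Nodes with interaction degree strictly greater than the threshold."""
    if degree_threshold < 0:
        raise ValueError("threshold must be >= 0")
    degree, _ = topology_stats(net)
    return set(np.flatnonzero(degree > degree_threshold).tolist())
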