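"""Similarity network fusion of the cell-level affinity views.

The consensus supervision target is obtained by the classic cross-view
diffusion: each view contributes a full transition matrix P (row-normalized
off-diagonal mass with 1/2 kept on the diagonal) and a k-NN-masked local
kernel S; the update ``P_v <- S_v @ mean(other P's) @ S_v.T`` is iterated a
fixed number of rounds and the final P's are averaged and symmetrized.
The fused affinity is binarized per-row (top-k) and OR-symmetrized into the
target adjacency used only for training supervision.
"""

from __future__ import annotations

import numpy as np

from magnet.config import ModelConfig
from magnet.data import SpatialDataset
from magnet.graphs import GraphError, TargetAdjacency


def _transition_matrix(W: np.ndarray) -> np.ndarray:
    """Full kernel P: off-diagonal row-normalized to 1/2, diagonal = 1/2."""
    n = W.shape[0]
    W = W.copy().astype(float)
    np.fill_diagonal(W, 0.0)
    rowsum = W.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    P = W / (2.0 * rowsum)
    np.fill_diagonal(P, 0.5)
    return P


def _local_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """k-NN-masked kernel S: each row keeps its K strongest neighbours,
    renormalized to sum 1."""
    n = W.shape[0]
    W = W.copy().astype(float)
    np.fill_diagonal(W, 0.0)
    S = np.zeros_like(W)
    for i in range(n):
        order = np.lexsort((np.arange(n), -W[i]))
        keep = [j for j in order if j != i][:K]
        S[i, keep] = W[i, keep]
    rowsum = S.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return S / rowsum


def snf_fuse(
    W_list: list[np.ndarray], K: int = 20, t: int = 20, mu: float = 0.5
) -> np.ndarray:
    """Fuse >= 2 same-size affinity matrices into one consensus affinity."""
    if len(W_list) < 2:
        raise GraphError("SNF needs at least two views")
    shapes = {W.shape for W in W_list}
    if len(shapes) != 1:
        raise GraphError(f"mismatched view shapes: {shapes}")
    n = W_list[0].shape[0]
    K = min(K, n - 1)
    P = [_transition_matrix(W) for W in W_list]
    S = [_local_kernel(W, K) for W in W_list]
    v = len(P)
    for _ in range(t):
        P_new = []
        for a in range(v):
            others = sum(P[b] for b in range(v) if b != a) / (v - 1)
            P_new.append(S[a] @ others @ S[a].T)
        P = P_new
    fused = sum(P) / v
    fused = (fused + fused.T) / 2.0
    return fused


def build_target(
    ds: SpatialDataset,
    W_spatial: np.ndarray,
    W_lr: np.ndarray,
    W_sim: np.ndarray,
    cfg: ModelConfig,
) -> TargetAdjacency:
    """Consensus binary supervision adjacency from the three views.

    The fused SNF affinity is thresholded per row (top ``k_neighbors``) and
    symmetrized by logical OR, so every cell ends with degree >= k.
    """
    fused = snf_fuse([W_spatial, W_lr, W_sim], K=cfg.snf_K, t=cfg.snf_t)
    n = fused.shape[0]
    A = np.zeros((n, n), dtype=np.int8)
    F = fused.copy()
    np.fill_diagonal(F, -np.inf)
    for i in range(n):
        order = np.lexsort((np.arange(n), -F[i]))[: cfg.k_neighbors]
        A[i, order] = 1
    A = np.maximum(A, A.T)  # logical OR symmetrization
    np.fill_diagonal(A, 0)
    return TargetAdjacency(A_target=A)
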