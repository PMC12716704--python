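"""Training objectives.

The composite objective is ``L_total = L_recon + w_c * L_contrast +
w_a * L_align`` with default weights (1, 0.1, 0.1):

* reconstruction -- binary cross-entropy of the inner-product decoder
  against the consensus target adjacency (over sampled edges during
  training; an exact full-matrix mode reproduces the 1/N^2 average);
* contrastive -- for each cell view, a symmetric InfoNCE term
  (temperature tau = 0.3) plus a margin-based term over hard negatives
  weighted by lambda = 0.1, aligning the view with the pooled gene
  embedding;
* center alignment -- mean squared distance of the fused embeddings from a
  trainable linear projection of the mean expression profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from magnet.autodiff import Tensor
from magnet.nn import l2_normalize_rows, log_sum_exp_rows


@dataclass
class ContrastiveConfig:
    tau: float = 0.3
    margin: float = 0.1
    lambda_margin: float = 0.1
    n_hard: int = 5

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")
        if self.n_hard < 1:
            raise ValueError("n_hard must be >= 1")


def info_nce(Z_v: Tensor, Z_g: Tensor, tau: float = 0.3) -> Tensor:
    """Symmetric InfoNCE between matched rows of two embedding sets.

    Rows are L2-normalized, similarities are cosine scaled by 1/tau, and the
    loss averages the two softmax cross-entropy directions over the batch.
    """
    n = Z_v.shape[0]
    if n == 0:
        raise ValueError("empty embedding batch")
    zv = l2_normalize_rows(Z_v)
    zg = l2_normalize_rows(Z_g)
    S = (zv @ zg.T) * (1.0 / tau)            # (N, N)
    diag = (zv * zg).sum(axis=1, keepdims=True) * (1.0 / tau)
    lse_rows = log_sum_exp_rows(S)           # anchor = view rows
    lse_cols = log_sum_exp_rows(S.T)         # anchor = gene rows
    loss = ((lse_rows - diag) + (lse_cols - diag)).sum() * (1.0 / (2 * n))
    return loss


def select_hard_negatives(
    anchors: np.ndarray, candidates: np.ndarray, n_hard: int = 5
) -> np.ndarray:
    """Indices of the most cosine-similar non-matching candidates per anchor.

    Returns an (N, min(n_hard, N-1)) integer array; ties break toward the
    lower index. Selection operates on raw arrays (no gradients flow
    through the choice of negatives).
    """
    a = anchors / np.maximum(np.linalg.norm(anchors, axis=1, keepdims=True), 1e-12)
    c = candidates / np.maximum(np.linalg.norm(candidates, axis=1, keepdims=True), 1e-12)
    sim = a @ c.T
    n = sim.shape[0]
    np.fill_diagonal(sim, -np.inf)  # exclude the matched index
    k = min(n_hard, n - 1)
    order = np.lexsort((np.broadcast_to(np.arange(n), sim.shape), -sim), axis=1)
    return order[:, :k]


def margin_loss(
    Z_v: Tensor,
    Z_g: Tensor,
    m: float = 0.1,
    neg_g: np.ndarray | None = None,
    neg_v: np.ndarray | None = None,
    n_hard: int = 5,
) -> Tensor:
    """Margin-based contrastive hinge over hard negatives, both directions.

    ``1/N sum_i [ sum_{j in H_g(i)} max(0, s(zv_i, zg_j) - s(zv_i, zg_i) + m)
    + sum_{j in H_v(i)} max(0, s(zg_i, zv_j) - s(zg_i, zv_i) + m) ]`` with
    cosine similarity s.
    """
    n = Z_v.shape[0]
    zv = l2_normalize_rows(Z_v)
    zg = l2_normalize_rows(Z_g)
    if neg_g is None:
        neg_g = select_hard_negatives(zv.data, zg.data, n_hard)
    if neg_v is None:
        neg_v = select_hard_negatives(zg.data, zv.data, n_hard)
    C = zv @ zg.T                                 # C[i, j] = s(zv_i, zg_j)
    pos = (zv * zg).sum(axis=1, keepdims=True)    # (N, 1)
    rows = np.repeat(np.arange(n), neg_g.shape[1])

    flat = C.reshape(n * n, 1)
    neg_sims_g = flat.gather_rows(rows * n + neg_g.ravel()).reshape(n, neg_g.shape[1])
    flat_T = C.T.reshape(n * n, 1)
    neg_sims_v = flat_T.gather_rows(
        np.repeat(np.arange(n), neg_v.shape[1]) * n + neg_v.ravel()
    ).reshape(n, neg_v.shape[1])

    h1 = (neg_sims_g - pos + m).relu().sum()
    h2 = (neg_sims_v - pos + m).relu().sum()
    return (h1 + h2) * (1.0 / n)


def contrastive_loss(
    views: dict[str, Tensor], Z_g: Tensor, cfg: ContrastiveConfig
) -> Tensor:
    """Sum over enabled views of InfoNCE + lambda * margin term."""
    total = None
    for Z_v in views.values():
        term = info_nce(Z_v, Z_g, cfg.tau)
        if cfg.lambda_margin > 0:
            term = term + cfg.lambda_margin * margin_loss(
                Z_v, Z_g, cfg.margin, n_hard=cfg.n_hard
            )
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no views enabled for the contrastive loss")
    return total


def center_alignment_loss(Z_final: Tensor, X_c: np.ndarray, P: Tensor) -> Tensor:
    """Mean squared distance of embeddings from the projected mean profile."""
    xbar = Tensor(X_c.mean(axis=0, keepdims=True))   # (1, G), constant
    anchor = xbar @ P                                 # (1, latent)
    resid = Z_final - anchor
    return (resid * resid).sum(axis=1, keepdims=True).mean()


# ---------------------------------------------------------------------------
# Decoder and reconstruction


def decode_adjacency(Z_final: np.ndarray) -> np.ndarray:
    """Inner-product decoder: ``sigmoid(z_i . z_j)``; exactly symmetric."""
    gram = Z_final @ Z_final.T
    return 1.0 / (1.0 + np.exp(-gram))


def _softplus(x: Tensor) -> Tensor:
    """Stable ``log(1 + exp(x)) = relu(x) + log1p(exp(-|x|))``."""
    ax = x.relu() + (-x).relu()
    return x.relu() + (1.0 + (-ax).exp()).log()


def edge_logits(Z: Tensor, edges: np.ndarray) -> Tensor:
    """Decoder logits ``z_i . z_j`` for an (E, 2) edge index array."""
    zi = Z.gather_rows(edges[:, 0])
    zj = Z.gather_rows(edges[:, 1])
    return (zi * zj).sum(axis=1, keepdims=True)


def reconstruction_loss(
    Z_final: Tensor,
    A_target: np.ndarray,
    pos_edges: np.ndarray | None = None,
    neg_edges: np.ndarray | None = None,
    full_matrix: bool = False,
) -> Tensor:
    """Binary cross-entropy of decoded probabilities against the target.

    With ``full_matrix=True`` the exact 1/N^2 average over every (i, j)
    entry is computed; otherwise the mean over the supplied positive and
    negative edge lists (the training mode, class-balanced by sampling).
    """
    if full_matrix:
        logits = Z_final @ Z_final.T
        y = Tensor(np.asarray(A_target, dtype=float))
        per_entry = _softplus(logits) - y * logits   # BCE-with-logits
        return per_entry.mean()
    if pos_edges is None or neg_edges is None or (len(pos_edges) + len(neg_edges)) == 0:
        raise ValueError("empty edge set for reconstruction loss")
    edges = np.vstack([pos_edges, neg_edges])
    y = np.r_[np.ones(len(pos_edges)), np.zeros(len(neg_edges))][:, None]
    logits = edge_logits(Z_final, edges)
    per_edge = _softplus(logits) - Tensor(y) * logits
    return per_edge.mean()


def total_loss(
    recon: Tensor,
    contrast: Tensor | float,
    align: Tensor | float,
    w_contrast: float = 0.1,
    w_align: float = 0.1,
) -> Tensor:
    """Weighted sum ``recon + w_c * contrast + w_a * align``."""
    out = recon
    if not (isinstance(contrast, float) and contrast == 0.0) and w_contrast > 0:
        out = out + w_contrast * contrast
    if not (isinstance(align, float) and align == 0.0) and w_align > 0:
        out = out + w_align * align
    return out
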