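"""Neural building blocks: GCN encoders, attention pooling, cross-attention
fusion. All layers are pure functions of :class:`~magnet.autodiff.Tensor`
inputs plus a parameter dictionary, so the whole model stays a flat
name -> array mapping that can be saved to a single NPZ container.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from magnet.autodiff import Parameter, Tensor, concat, spmm

LN_EPS = 1e-5


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def normalize_adjacency(A: sparse.spmatrix | np.ndarray) -> sparse.csr_matrix:
    """Renormalized propagation operator ``D^-1/2 (A + I) D^-1/2``."""
    A = sparse.csr_matrix(A, dtype=float)
    n = A.shape[0]
    A_tilde = A + sparse.eye(n, format="csr")
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sparse.diags(d_inv_sqrt)
    return sparse.csr_matrix(D @ A_tilde @ D)


def gcn_layer(
    A_norm: sparse.csr_matrix, Z_in: Tensor, W: Tensor, activation: str = "relu"
) -> Tensor:
    """One GCN propagation step: ``act(A_norm @ Z @ W)``."""
    out = spmm(A_norm, Z_in) @ W
    if activation == "relu":
        return out.relu()
    if activation == "linear":
        return out
    raise ValueError(f"unknown activation {activation!r}")


def gcn_encode(A_norm: sparse.csr_matrix, X: Tensor, W0: Tensor, W1: Tensor) -> Tensor:
    """Two-layer bottleneck GCN: ReLU hidden layer, linear 32-d output."""
    h = gcn_layer(A_norm, X, W0, "relu")
    return gcn_layer(A_norm, h, W1, "linear")


def softmax_rows(x: Tensor) -> Tensor:
    """Numerically stable row softmax (shift by the row max, a constant)."""
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def log_sum_exp_rows(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    return (x - shift).exp().sum(axis=-1, keepdims=True).log() + shift


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = LN_EPS) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps).pow(-0.5) * gamma + beta


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    sq = (x * x).sum(axis=-1, keepdims=True)
    return x * (sq + eps).pow(-0.5)


# ---------------------------------------------------------------------------
# Attention pooling of gene nodes to cell level


def make_pool_matrix(n_cells: int, k_genes: int) -> sparse.csr_matrix:
    """(N, N*k) summing matrix mapping each cell's gene slots to the cell."""
    rows = np.repeat(np.arange(n_cells), k_genes)
    cols = np.arange(n_cells * k_genes)
    return sparse.csr_matrix(
        (np.ones(n_cells * k_genes), (rows, cols)), shape=(n_cells, n_cells * k_genes)
    )


def attention_pool(
    Zg: Tensor,
    n_cells: int,
    k_genes: int,
    W1: Tensor,
    b1: Tensor,
    W2: Tensor,
    b2: Tensor,
    return_weights: bool = False,
):
    """Per-cell softmax attention over the cell's ``k_genes`` gene embeddings.

    ``Zg`` is the (N*k, 32) gene-node embedding; a shared two-layer MLP
    (tanh nonlinearity) scores every gene node, scores are softmax-normalized
    within each cell, and the cell representation is the convex combination
    of its gene embeddings.
    """
    scores = ((Zg @ W1 + b1).tanh() @ W2 + b2)          # (N*k, 1)
    beta = softmax_rows(scores.reshape(n_cells, k_genes))  # (N, k)
    beta_flat = beta.reshape(n_cells * k_genes, 1)
    pooled = spmm(make_pool_matrix(n_cells, k_genes), Zg * beta_flat)
    if return_weights:
        return pooled, beta.data.copy()
    return pooled


# ---------------------------------------------------------------------------
# Cell-gene cross attention


def cross_attention_branch(
    Zc: Tensor,
    Zg: Tensor,
    params: dict[str, Tensor],
    prefix: str,
    heads: int,
    return_attention: bool = False,
):
    """Multi-head scaled dot-product attention: cells query gene embeddings.

    Per head h, ``alpha = softmax(Q K^T / sqrt(d_k))`` over all N pooled
    gene rows and the head output is ``alpha @ V``; heads are concatenated
    and projected by ``W_o``.
    """
    d = Zc.shape[1]
    d_k = d // heads
    outs = []
    attn_maps = []
    for h in range(heads):
        Q = Zc @ params[f"{prefix}_Wq{h}"]
        K = Zg @ params[f"{prefix}_Wk{h}"]
        V = Zg @ params[f"{prefix}_Wv{h}"]
        logits = (Q @ K.T) * (1.0 / np.sqrt(d_k))
        alpha = softmax_rows(logits)
        outs.append(alpha @ V)
        if return_attention:
            attn_maps.append(alpha.data.copy())
    fused = concat(outs, axis=-1) @ params[f"{prefix}_Wo"]
    if return_attention:
        return fused, attn_maps
    return fused


def transformer_block(Z_attn: Tensor, Zc: Tensor, params: dict[str, Tensor], prefix: str) -> Tensor:
    """Residual + layer norm + position-wise FFN (GELU) + second residual."""
    y = layer_norm(Zc + Z_attn, params[f"{prefix}_ln_g"], params[f"{prefix}_ln_b"])
    ffn = (y @ params[f"{prefix}_W1"] + params[f"{prefix}_b1"]).gelu() @ params[
        f"{prefix}_W2"
    ] + params[f"{prefix}_b2"]
    return y + ffn


def gated_fusion(
    branches: list[Tensor],
    params: dict[str, Tensor],
    return_weights: bool = False,
):
    """Convex combination of branch outputs with per-cell softmax gates."""
    cat = concat(branches, axis=-1)
    logits = (cat @ params["gate_W1"] + params["gate_b1"]).tanh() @ params[
        "gate_W2"
    ] + params["gate_b2"]                                 # (N, n_branches)
    w = softmax_rows(logits)
    out = None
    for k, Zf in enumerate(branches):
        term = Zf * _column(w, k)
        out = term if out is None else out + term
    if return_weights:
        return out, w.data.copy()
    return out


def _column(x: Tensor, k: int) -> Tensor:
    """Differentiable selection of column k as an (N, 1) tensor."""
    n, m = x.shape
    e = np.zeros((m, 1))
    e[k, 0] = 1.0
    return x @ Tensor(e)


def init_branch_params(
    rng: np.random.Generator, params: dict[str, Parameter], prefix: str, d: int, heads: int
) -> None:
    d_k = d // heads
    for h in range(heads):
        params[f"{prefix}_Wq{h}"] = Parameter(glorot(rng, d, d_k))
        params[f"{prefix}_Wk{h}"] = Parameter(glorot(rng, d, d_k))
        params[f"{prefix}_Wv{h}"] = Parameter(glorot(rng, d, d_k))
    # residual-branch outputs start at zero so each branch begins as the
    # identity-plus-norm path and the attention/FFN signal grows in smoothly
    params[f"{prefix}_Wo"] = Parameter(np.zeros((heads * d_k, d)))
    params[f"{prefix}_ln_g"] = Parameter(np.ones((1, d)))
    params[f"{prefix}_ln_b"] = Parameter(np.zeros((1, d)))
    params[f"{prefix}_W1"] = Parameter(glorot(rng, d, 4 * d))
    params[f"{prefix}_b1"] = Parameter(np.zeros((1, 4 * d)))
    params[f"{prefix}_W2"] = Parameter(np.zeros((4 * d, d)))
    params[f"{prefix}_b2"] = Parameter(np.zeros((1, d)))


def save_params(params: dict[str, Parameter], path: str) -> None:
    np.savez(path, **{k: p.data for k, p in params.items()})


def load_params(path: str) -> dict[str, Parameter]:
    with np.load(path) as npz:
        return {k: Parameter(npz[k]) for k in npz.files}
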