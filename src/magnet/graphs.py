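"""Construction of the cell-level view graphs and the gene-level block graph.

Three weighted cell-cell affinity views are built from a spatial dataset:

* ``spatial`` -- adaptive Gaussian kernel on physical distance,
  ``W_ij = exp(-d_ij^2 / (2 sigma_i^2))`` with a per-cell bandwidth equal to
  the distance to the cell's nearest neighbour;
* ``lr`` -- ligand-receptor signalling potential,
  ``S_ij = E_l'(i) * E_r'(j) * exp(-d_ij^2 / (2 sigma^2))`` summed over the
  pairs that pass a permutation test;
* ``similarity`` -- transcriptional similarity in PCA space using the
  locally adaptive exponential kernel
  ``P(j|i) = exp(-max(0, d_ij - rho_i) / (sigma_i + eps))`` symmetrized by
  the probabilistic OR ``p + q - p*q``.

Each view is sparsified to a binary adjacency by keeping the top-k outgoing
edges per cell (k = 5 by default). The gene-level graph stacks one small
gene regulatory network per cell into a block-diagonal adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.io import mmread
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from magnet.config import ModelConfig
from magnet.data import LigandReceptorDB, SpatialDataset, normalize_expression

logger = logging.getLogger(__name__)

EPS = 1e-8


class GraphError(ValueError):
    """Raised for graphs that violate structural contracts."""


@dataclass
class ViewGraph:
    """One cell-level view: weights ``W``, binary adjacency ``A``, view tag."""

    W: np.ndarray
    A: sparse.csr_matrix
    view: str

    def __post_init__(self) -> None:
        if self.view not in ("spatial", "lr", "similarity"):
            raise GraphError(f"unknown view tag {self.view!r}")
        if not np.all(np.isfinite(self.W)):
            raise GraphError("view weights contain NaN/Inf")
        A = sparse.csr_matrix(self.A)
        if A.diagonal().any():
            raise GraphError("adjacency has self-loops")
        if A.nnz == 0:
            raise GraphError(f"empty {self.view} graph")
        self.A = A


@dataclass
class SimilarityParams:
    """Per-cell local-density parameters of the similarity kernel."""

    rho: np.ndarray    # distance to nearest neighbour
    sigma: np.ndarray  # distance to the kth nearest neighbour
    epsilon: float = EPS

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise GraphError("epsilon must be positive")
        if np.any(self.rho > self.sigma + 1e-12):
            raise GraphError("rho_i must not exceed sigma_i")


@dataclass
class LRScoreTable:
    """Per ligand-receptor pair: score matrix, total score and permutation p."""

    pair_indices: list[tuple[int, int]]
    scores: list[np.ndarray]
    pvalues: list[float]
    significant: list[bool]

    @property
    def aggregate(self) -> np.ndarray:
        """Sum of the score matrices of all significant pairs."""
        if not self.scores:
            raise GraphError("no scored pairs")
        total = np.zeros_like(self.scores[0])
        for s, sig in zip(self.scores, self.significant):
            if sig:
                total += s
        return total


@dataclass
class GeneBlockGraph:
    """Block-diagonal gene-gene adjacency over all cells' selected genes."""

    A_g: sparse.csr_matrix
    X_g: np.ndarray | None
    gene_map: list[list[int]]
    lr_directed_edges: list[tuple[int, int, int]] = field(default_factory=list)
    # (cell, local ligand slot, local receptor slot)

    def __post_init__(self) -> None:
        k = len(self.gene_map[0])
        if any(len(g) != k for g in self.gene_map):
            raise GraphError("every cell block must have the same gene count")
        m = len(self.gene_map) * k
        if self.A_g.shape != (m, m):
            raise GraphError(f"A_g shape {self.A_g.shape} != ({m}, {m})")
        coo = sparse.coo_matrix(self.A_g)
        if np.any(coo.row // k != coo.col // k):
            raise GraphError("A_g links gene nodes of different cells")
        if self.X_g is not None and not np.all(np.isfinite(self.X_g)):
            raise GraphError("X_g contains NaN/Inf")

    @property
    def k_genes(self) -> int:
        return len(self.gene_map[0])

    @property
    def n_cells(self) -> int:
        return len(self.gene_map)


@dataclass
class TargetAdjacency:
    """Binary symmetric supervision matrix (never a model input)."""

    A_target: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A_target)
        if not np.array_equal(A, A.T):
            raise GraphError("target adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise GraphError("target adjacency must have zero diagonal")
        if A.sum() == 0:
            raise GraphError("target adjacency has no positive edge")
        self.A_target = A.astype(np.int8)

    def positive_edges(self) -> np.ndarray:
        """Unique undirected positives as an (E, 2) array with i < j."""
        iu, ju = np.triu_indices_from(self.A_target, k=1)
        mask = self.A_target[iu, ju] > 0
        return np.c_[iu[mask], ju[mask]]


# ---------------------------------------------------------------------------
# Spatial view


def spatial_kernel(coords: np.ndarray, m: int = 1) -> np.ndarray:
    """Adaptive Gaussian kernel; bandwidth = distance to the m-th neighbour."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise GraphError("need at least 2 cells")
    if m > n - 1:
        raise GraphError(f"bandwidth rank m={m} exceeds N-1={n - 1}")
    d = cdist(coords, coords)
    # m-th smallest off-diagonal distance per row
    off = np.sort(d + np.where(np.eye(n, dtype=bool), np.inf, 0.0), axis=1)
    sigma = off[:, m - 1]
    sigma = np.where(sigma <= 0, EPS, sigma)
    W = np.exp(-(d**2) / (2 * sigma[:, None] ** 2))
    np.fill_diagonal(W, 0.0)
    return W


def topk_sparsify(W: np.ndarray, k: int, exclude_self: bool = True) -> sparse.csr_matrix:
    """Keep each row's k largest strictly positive off-diagonal weights.

    Ties break toward the smaller column index. Rows with fewer than k
    strictly positive weights keep only those (zero affinity is not
    evidence of adjacency).
    """
    if k < 1:
        raise GraphError("k must be >= 1")
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    rows, cols = [], []
    for i in range(n):
        w = W[i].copy()
        if exclude_self:
            w[i] = 0.0
        pos = np.flatnonzero(w > 0)
        if pos.size == 0:
            continue
        order = pos[np.lexsort((pos, -w[pos]))]  # by -weight then column index
        keep = order[:k]
        rows.extend([i] * len(keep))
        cols.extend(keep.tolist())
    A = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.int8
    )
    return A


def build_spatial_graph(ds: SpatialDataset, cfg: ModelConfig) -> ViewGraph:
    W = spatial_kernel(ds.coords, m=cfg.bandwidth_rank)
    A = topk_sparsify(W, cfg.k_neighbors)
    return ViewGraph(W=W, A=A, view="spatial")


# ---------------------------------------------------------------------------
# Ligand-receptor view


def mean_nn_distance(coords: np.ndarray) -> float:
    """Mean nearest-neighbour distance; the tissue's characteristic spacing."""
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    return float(np.mean(d.min(axis=1)))


def lr_pair_score(
    expr_norm: np.ndarray,
    coords: np.ndarray,
    pair: tuple[int, int],
    sigma_global: float,
) -> np.ndarray:
    """Directed score matrix ``S_ij = E_l'(i) E_r'(j) exp(-d_ij^2/(2 sigma^2))``."""
    if sigma_global <= 0:
        raise GraphError("sigma_global must be positive")
    lig, rec = pair
    d = cdist(coords, coords)
    K = np.exp(-(d**2) / (2 * sigma_global**2))
    S = np.outer(expr_norm[:, lig], expr_norm[:, rec]) * K
    np.fill_diagonal(S, 0.0)
    return S


def permutation_pvalue(
    score_obs: float,
    expr_norm: np.ndarray,
    pair: tuple[int, int],
    coords: np.ndarray,
    n_perm: int = 100,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for a ligand-receptor pair's total score.

    The null re-pairs receptor expression with cell positions: the receptor
    column is permuted across cells, the score matrix recomputed, and the
    total off-diagonal score compared with the observed one. The add-one
    convention gives ``p = (1 + #{null >= obs}) / (1 + n_perm)`` in (0, 1].
    """
    if n_perm < 1:
        raise GraphError("n_perm must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lig, rec = pair
    sigma = mean_nn_distance(coords)
    d = cdist(coords, coords)
    K = np.exp(-(d**2) / (2 * sigma**2))
    np.fill_diagonal(K, 0.0)
    lig_v = expr_norm[:, lig]
    rec_v = expr_norm[:, rec]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(rec_v))
        null = float(lig_v @ K @ rec_v[perm])
        if null >= score_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def score_lr_pairs(
    ds: SpatialDataset,
    lr_db: LigandReceptorDB,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
) -> LRScoreTable:
    """Score every mappable ligand-receptor pair and permutation-test it."""
    pairs = lr_db.mappable_pairs(ds)
    skipped = len(lr_db) - len(pairs)
    if skipped:
        logger.info("skipping %d LR pairs absent from the dataset", skipped)
    if not pairs:
        raise GraphError(
            "no ligand-receptor pair maps to dataset genes; "
            "supply a matching (e.g. toy) LR table"
        )
    expr_norm = normalize_expression(ds.expr, "minmax_per_gene")
    sigma = mean_nn_distance(ds.coords)
    rng = np.random.default_rng(seed)
    scores, pvals, sig = [], [], []
    for pair in pairs:
        S = lr_pair_score(expr_norm, ds.coords, pair, sigma)
        obs = float(S.sum())
        p = permutation_pvalue(obs, expr_norm, pair, ds.coords, n_perm, rng)
        scores.append(S)
        pvals.append(p)
        sig.append(p < alpha)
    return LRScoreTable(pair_indices=pairs, scores=scores, pvalues=pvals, significant=sig)


def build_lr_graph(
    ds: SpatialDataset,
    lr_db: LigandReceptorDB,
    cfg: ModelConfig,
    alpha: float | None = None,
    n_perm: int | None = None,
) -> ViewGraph:
    table = score_lr_pairs(
        ds,
        lr_db,
        alpha=cfg.alpha if alpha is None else alpha,
        n_perm=cfg.n_perm if n_perm is None else n_perm,
        seed=cfg.seed,
    )
    W = table.aggregate
    if not np.any(W > 0):
        raise GraphError(
            "empty LR graph: no ligand-receptor pair passed the permutation test"
        )
    A = topk_sparsify(W, cfg.k_neighbors)
    return ViewGraph(W=W, A=A, view="lr")


# ---------------------------------------------------------------------------
# Transcriptional similarity view


def conditional_similarity(
    d_ij: np.ndarray | float,
    rho_i: np.ndarray | float,
    sigma_i: np.ndarray | float,
    eps: float = EPS,
) -> np.ndarray | float:
    """Locally adaptive membership ``P(j|i) = exp(-max(0, d-rho)/(sigma+eps))``."""
    return np.exp(-np.maximum(0.0, d_ij - rho_i) / (np.asarray(sigma_i) + eps))


def symmetrize_similarity(p_ij, p_ji):
    """Probabilistic OR: ``p + q - p*q``; symmetric, bounded in [0, 1]."""
    return p_ij + p_ji - p_ij * p_ji


def build_similarity_graph(
    ds: SpatialDataset,
    cfg: ModelConfig,
    pca_dim: int | None = None,
    knn_for_sigma: int | None = None,
) -> ViewGraph:
    """Similarity view from PCA-reduced expression.

    Expression is library-size/log1p normalized, reduced to (at most) 32
    principal components, and converted to a symmetric affinity with the
    adaptive kernel above; rho is the nearest-neighbour distance and sigma
    the k-th-neighbour distance in PCA space.
    """
    n = ds.n_cells
    if n < 3:
        raise GraphError("similarity graph needs at least 3 cells")
    pca_dim = cfg.pca_dim if pca_dim is None else pca_dim
    k = cfg.k_neighbors if knn_for_sigma is None else knn_for_sigma
    if k >= n - 1:
        k = n - 2
        logger.warning("knn_for_sigma reduced to %d for N=%d", k, n)

    expr = normalize_expression(ds.expr, "library_size_log1p")
    n_comp = min(n - 1, ds.n_genes, pca_dim)
    Xs = PCA(n_components=n_comp, random_state=0).fit_transform(expr)
    d = cdist(Xs, Xs)
    off = np.sort(d + np.where(np.eye(n, dtype=bool), np.inf, 0.0), axis=1)
    rho = off[:, 0]
    sigma = off[:, k - 1]
    P = conditional_similarity(d, rho[:, None], sigma[:, None])
    W = symmetrize_similarity(P, P.T)
    np.fill_diagonal(W, 0.0)
    A = topk_sparsify(W, cfg.k_neighbors)
    return ViewGraph(W=W, A=A, view="similarity")


# ---------------------------------------------------------------------------
# Gene-level block graph


def select_genes_per_cell(
    ds: SpatialDataset, lr_db: LigandReceptorDB, k_genes: int = 30
) -> list[list[int]]:
    """Per-cell ordered gene panels of size ``k_genes``.

    Ligand-receptor pairs mappable to the dataset are admitted first, whole
    pairs together, ordered by the cell's expression of the stronger member;
    once the next whole pair would overflow the budget, remaining slots are
    filled with the cell's most highly expressed genes not already chosen
    (ties toward the lower gene index).
    """
    g = ds.n_genes
    if k_genes > g:
        raise GraphError(f"k_genes={k_genes} exceeds G={g}")
    pairs = lr_db.mappable_pairs(ds)
    gene_map: list[list[int]] = []
    for i in range(ds.n_cells):
        expr_i = ds.expr[i]
        chosen: list[int] = []
        chosen_set: set[int] = set()
        pair_scores = [
            (max(expr_i[l], expr_i[r]), pi) for pi, (l, r) in enumerate(pairs)
        ]
        pair_scores.sort(key=lambda t: (-t[0], t[1]))
        for _, pi in pair_scores:
            l, r = pairs[pi]
            new = [x for x in (l, r) if x not in chosen_set]
            if len(chosen) + len(new) > k_genes:
                break  # keep whole pairs only; no partial pair admission
            for x in new:
                chosen.append(x)
                chosen_set.add(x)
        if len(chosen) < k_genes:
            rest = [j for j in range(g) if j not in chosen_set]
            rest.sort(key=lambda j: (-expr_i[j], j))
            fill = rest[: k_genes - len(chosen)]
            chosen.extend(fill)
        gene_map.append(chosen[:k_genes])
    return gene_map


def infer_cell_grns(
    ds: SpatialDataset,
    gene_map: list[list[int]],
    provider: str = "default_corr",
    lr_db: LigandReceptorDB | None = None,
    r_min: float = 0.6,
    n_neighbors: int = 5,
    external_path: str | None = None,
) -> GeneBlockGraph:
    """Per-cell gene regulatory networks stacked block-diagonally.

    ``default_corr`` estimates each cell's network from the absolute Pearson
    correlation of its selected genes over the cell's spatial neighbourhood
    (the cell plus its ``n_neighbors`` nearest cells), keeping edges with
    ``|r| >= r_min``. ``external_mtx`` loads a precomputed block-diagonal
    adjacency (e.g. from a dedicated GRN estimator) and validates the block
    structure. Edges whose endpoints form a known ligand-receptor pair are
    annotated with ligand-to-receptor direction.
    """
    if len(gene_map) != ds.n_cells:
        raise GraphError("gene_map must cover every cell")
    k = len(gene_map[0])
    n = ds.n_cells
    m = n * k

    if provider == "external_mtx":
        if external_path is None:
            raise GraphError("external_mtx provider needs external_path")
        A = sparse.csr_matrix(mmread(external_path))
        if A.shape != (m, m):
            raise GraphError(f"external matrix shape {A.shape} != ({m}, {m})")
        coo = A.tocoo()
        if np.any(coo.row // k != coo.col // k):
            raise GraphError("external matrix has cross-cell entries")
        blocks_adj = A
    elif provider == "default_corr":
        d = cdist(ds.coords, ds.coords)
        np.fill_diagonal(d, np.inf)
        expr = normalize_expression(ds.expr, "library_size_log1p")
        rows, cols = [], []
        for i in range(n):
            nbrs = np.argsort(d[i], kind="stable")[:n_neighbors]
            sample = expr[np.r_[i, nbrs]][:, gene_map[i]]
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(sample.T)
            r = np.nan_to_num(r, nan=0.0)
            np.fill_diagonal(r, 0.0)
            a, b = np.nonzero(np.abs(r) >= r_min)
            rows.extend((i * k + a).tolist())
            cols.extend((i * k + b).tolist())
        blocks_adj = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(m, m), dtype=np.int8
        )
    else:
        raise GraphError(f"unknown GRN provider {provider!r}")

    directed: list[tuple[int, int, int]] = []
    if lr_db is not None:
        pair_set = set(lr_db.mappable_pairs(ds))
        for i in range(n):
            local = {gene: slot for slot, gene in enumerate(gene_map[i])}
            for lig, rec in pair_set:
                if lig in local and rec in local:
                    sl, sr = local[lig], local[rec]
                    if blocks_adj[i * k + sl, i * k + sr] != 0:
                        directed.append((i, sl, sr))

    return GeneBlockGraph(
        A_g=blocks_adj, X_g=None, gene_map=gene_map, lr_directed_edges=directed
    )
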