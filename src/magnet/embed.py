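"""node2vec-style gene-node embeddings.

Biased second-order random walks over the block-diagonal gene graph followed
by skip-gram with negative sampling give each gene node a dense feature
vector encoding its local regulatory topology. With the default return /
in-out parameters p = q = 1 the walks reduce to uniform first-order walks.
Isolated nodes receive the zero vector; everything is deterministic given
the seed.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.special import expit


def _build_adjacency_lists(A: sparse.spmatrix) -> list[np.ndarray]:
    A = sparse.csr_matrix(A)
    A = ((A + A.T) > 0).astype(np.int8)  # walks use the undirected structure
    return [A.indices[A.indptr[i] : A.indptr[i + 1]] for i in range(A.shape[0])]


def random_walks(
    A: sparse.spmatrix,
    n_walks: int = 10,
    walk_length: int = 20,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Generate biased random walks from every non-isolated node.

    The uniform case (p = q = 1) runs fully vectorized over all walks at
    once; the general biased case falls back to a per-step loop.
    """
    rng = np.random.default_rng(seed)
    nbrs = _build_adjacency_lists(A)
    nodes = np.asarray([v for v in range(len(nbrs)) if len(nbrs[v]) > 0])
    if len(nodes) == 0:
        return []
    if p == 1.0 and q == 1.0:
        deg = np.asarray([len(nb) for nb in nbrs])
        max_deg = deg.max()
        pad = np.zeros((len(nbrs), max_deg), dtype=np.int64)
        for v, nb in enumerate(nbrs):
            if len(nb):
                pad[v, : len(nb)] = nb
        starts = np.tile(nodes, n_walks)
        steps = [starts]
        cur = starts
        for _ in range(walk_length - 1):
            pick = (rng.random(len(cur)) * deg[cur]).astype(np.int64)
            cur = pad[cur, pick]
            steps.append(cur)
        mat = np.stack(steps, axis=1)           # (n_walks*|nodes|, walk_length)
        return list(mat)
    walks: list[np.ndarray] = []
    for _ in range(n_walks):
        for start in nodes:
            walk = [int(start)]
            while len(walk) < walk_length:
                cur = walk[-1]
                cands = nbrs[cur]
                if len(cands) == 0:
                    break
                if len(walk) == 1:
                    nxt = cands[rng.integers(len(cands))]
                else:
                    prev = walk[-2]
                    w = np.where(
                        cands == prev,
                        1.0 / p,
                        np.where(np.isin(cands, nbrs[prev]), 1.0, 1.0 / q),
                    )
                    w = w / w.sum()
                    nxt = cands[rng.choice(len(cands), p=w)]
                walk.append(int(nxt))
            walks.append(np.asarray(walk, dtype=np.int64))
    return walks


def _skipgram_pairs(walks: list[np.ndarray], window: int, rng: np.random.Generator):
    lengths = {len(w) for w in walks}
    if len(lengths) == 1:
        mat = np.stack(walks)
        cs, os_ = [], []
        for off in range(1, window + 1):
            if off >= mat.shape[1]:
                break
            a, b = mat[:, :-off].ravel(), mat[:, off:].ravel()
            cs.extend((a, b))
            os_.extend((b, a))
        centers = np.concatenate(cs)
        contexts = np.concatenate(os_)
    else:
        c_list, o_list = [], []
        for walk in walks:
            L = len(walk)
            for t in range(L):
                for u in range(max(0, t - window), min(L, t + window + 1)):
                    if u != t:
                        c_list.append(walk[t])
                        o_list.append(walk[u])
        centers = np.asarray(c_list, dtype=np.int64)
        contexts = np.asarray(o_list, dtype=np.int64)
    order = rng.permutation(len(centers))
    return centers[order], contexts[order]


def _scatter_add(target: np.ndarray, idx: np.ndarray, updates: np.ndarray) -> None:
    """``target[idx] += updates`` with duplicate indices, via sparse matmul."""
    b = len(idx)
    S = sparse.csr_matrix(
        (np.ones(b), (idx, np.arange(b))), shape=(target.shape[0], b)
    )
    target += S @ updates


def skipgram_embed(
    walks: list[np.ndarray],
    n_nodes: int,
    dim: int = 64,
    window: int = 5,
    n_negative: int = 5,
    lr: float = 0.025,
    epochs: int = 1,
    batch: int = 65536,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Skip-gram with negative sampling, trained by minibatch SGD.

    The center/context pair list is shuffled and capped at ``max_pairs``
    (walks over small graph blocks are highly redundant, so a subsample
    carries the same co-occurrence signal at a fraction of the cost).
    Arrays are float32: embedding quality, not precision, is the target.
    """
    rng = np.random.default_rng(seed)
    emb_in = ((rng.random((n_nodes, dim), dtype=np.float32) - 0.5) / dim)
    emb_out = np.zeros((n_nodes, dim), dtype=np.float32)
    centers, contexts = _skipgram_pairs(walks, window, rng)
    if len(centers) == 0:
        return np.zeros((n_nodes, dim))
    centers, contexts = centers[:max_pairs], contexts[:max_pairs]
    # negative-sampling distribution: unigram^0.75 over walk occurrences
    counts = np.bincount(np.concatenate(walks), minlength=n_nodes).astype(float)
    noise = counts**0.75
    noise /= noise.sum()
    n_pairs = len(centers)
    for _ in range(epochs):
        for s in range(0, n_pairs, batch):
            c = centers[s : s + batch]
            o = contexts[s : s + batch]
            neg = rng.choice(n_nodes, size=(len(c), n_negative), p=noise)
            vc = emb_in[c]                               # (B, d)
            vo = emb_out[o]                              # (B, d)
            vn = emb_out[neg]                            # (B, K, d)
            vc, vo, vn = vc.astype(np.float32), vo, vn
            pos_score = expit(np.sum(vc * vo, axis=1))
            neg_score = expit(np.einsum("bd,bkd->bk", vc, vn))
            g_pos = (pos_score - 1.0)[:, None]           # d/dscore of -log sigma
            g_neg = neg_score[:, :, None]
            grad_c = g_pos * vo + np.einsum("bk,bkd->bd", neg_score, vn)
            _scatter_add(emb_in, c, -lr * grad_c)
            _scatter_add(emb_out, o, -lr * (g_pos * vc))
            _scatter_add(
                emb_out, neg.ravel(), (-lr * (g_neg * vc[:, None, :])).reshape(-1, dim)
            )
    return emb_in


def embed_gene_nodes(
    A_g: sparse.spmatrix,
    d: int = 64,
    n_walks: int = 10,
    walk_length: int = 20,
    window: int = 5,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """node2vec features for every gene node of the block graph.

    Returns an (M, d) matrix; isolated nodes map to the zero vector and the
    result is deterministic given ``seed``.
    """
    n_nodes = A_g.shape[0]
    walks = random_walks(A_g, n_walks, walk_length, p, q, seed)
    emb = skipgram_embed(walks, n_nodes, dim=d, window=window, seed=seed)
    degrees = np.asarray((sparse.csr_matrix(A_g) != 0).sum(axis=1)).ravel() + np.asarray(
        (sparse.csr_matrix(A_g) != 0).sum(axis=0)
    ).ravel()
    emb[degrees == 0] = 0.0
    return emb
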