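"""End-to-end model: view encoders, gene pooling, cross-attention fusion.

The model owns a flat parameter dictionary and caches the constant inputs
(normalized adjacencies, feature matrices). A forward pass produces the
view embeddings, the pooled gene embedding, and the fused final embedding,
plus gate/attention weights for interpretation.
"""

from __future__ import annotations

import numpy as np

from magnet.autodiff import Parameter, Tensor, concat
from magnet.config import ModelConfig
from magnet.graphs import GeneBlockGraph, ViewGraph
from magnet.nn import (
    attention_pool,
    cross_attention_branch,
    gated_fusion,
    gcn_encode,
    glorot,
    init_branch_params,
    normalize_adjacency,
    transformer_block,
)


class MagnetModel:
    """Multi-view graph autoencoder with cell-gene cross attention."""

    def __init__(
        self,
        views: dict[str, ViewGraph],
        gene_graph: GeneBlockGraph,
        X_c: np.ndarray,
        X_g: np.ndarray,
        cfg: ModelConfig,
    ):
        enabled = [v for v in cfg.views_enabled if v in views]
        if not enabled:
            raise ValueError("no enabled view present")
        self.cfg = cfg
        self.view_names = enabled
        self.A_norm = {v: normalize_adjacency(views[v].A) for v in enabled}
        self.Ag_norm = normalize_adjacency(gene_graph.A_g)
        self.X_c = np.asarray(X_c, dtype=float)
        self.X_g = np.asarray(X_g, dtype=float)
        self.n_cells = self.X_c.shape[0]
        self.k_genes = gene_graph.k_genes
        self.params: dict[str, Parameter] = {}
        self._init_params()

    def _init_params(self) -> None:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        d, hid, g = cfg.latent_dim, cfg.hidden_dim, self.X_c.shape[1]
        p = self.params
        for v in self.view_names:
            p[f"gcn_{v}_W0"] = Parameter(glorot(rng, g, hid))
            p[f"gcn_{v}_W1"] = Parameter(glorot(rng, hid, d))
        p["gcn_gene_W0"] = Parameter(glorot(rng, self.X_g.shape[1], hid))
        p["gcn_gene_W1"] = Parameter(glorot(rng, hid, d))
        # gene attention-pool MLP: d -> 16 -> 1 with tanh
        p["pool_W1"] = Parameter(glorot(rng, d, 16))
        p["pool_b1"] = Parameter(np.zeros((1, 16)))
        p["pool_W2"] = Parameter(glorot(rng, 16, 1))
        p["pool_b2"] = Parameter(np.zeros((1, 1)))
        nb = len(self.view_names)
        if cfg.use_attention:
            for v in self.view_names:
                init_branch_params(rng, p, f"attn_{v}", d, cfg.heads)
            p["gate_W1"] = Parameter(glorot(rng, nb * d, 16))
            p["gate_b1"] = Parameter(np.zeros((1, 16)))
            p["gate_W2"] = Parameter(glorot(rng, 16, nb))
            p["gate_b2"] = Parameter(np.zeros((1, nb)))
        else:
            # ablation fallback: linear map of [mean(view embeddings), Zg']
            p["fallback_W"] = Parameter(glorot(rng, 2 * d, d))
        if cfg.use_align:
            p["align_P"] = Parameter(glorot(rng, g, d))

    def forward(self, return_aux: bool = False):
        """Compute view embeddings, pooled gene embedding and fusion.

        Returns (Z_views, Z_g_pooled, Z_final[, aux]) where Z_views maps view
        name -> (N, d) Tensor and aux carries gate weights / attention maps
        (numpy) when requested.
        """
        cfg = self.cfg
        p = self.params
        Xc = Tensor(self.X_c)
        Xg = Tensor(self.X_g)
        Z_views = {
            v: gcn_encode(self.A_norm[v], Xc, p[f"gcn_{v}_W0"], p[f"gcn_{v}_W1"])
            for v in self.view_names
        }
        Zg_nodes = gcn_encode(self.Ag_norm, Xg, p["gcn_gene_W0"], p["gcn_gene_W1"])
        Zg_pooled, beta = attention_pool(
            Zg_nodes, self.n_cells, self.k_genes,
            p["pool_W1"], p["pool_b1"], p["pool_W2"], p["pool_b2"],
            return_weights=True,
        )
        aux: dict = {"pool_beta": beta}
        if cfg.use_attention:
            branches = []
            for v in self.view_names:
                att, maps = cross_attention_branch(
                    Z_views[v], Zg_pooled, p, f"attn_{v}", cfg.heads,
                    return_attention=True,
                )
                aux[f"attention_{v}"] = maps
                branches.append(transformer_block(att, Z_views[v], p, f"attn_{v}"))
            if len(branches) == 1:
                Z_final = branches[0]
                aux["gate_weights"] = np.ones((self.n_cells, 1))
            else:
                Z_final, w = gated_fusion(branches, p, return_weights=True)
                aux["gate_weights"] = w
        else:
            mean_views = None
            for v in self.view_names:
                mean_views = Z_views[v] if mean_views is None else mean_views + Z_views[v]
            mean_views = mean_views * (1.0 / len(self.view_names))
            Z_final = concat([mean_views, Zg_pooled], axis=-1) @ p["fallback_W"]
        if return_aux:
            return Z_views, Zg_pooled, Z_final, aux
        return Z_views, Zg_pooled, Z_final
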