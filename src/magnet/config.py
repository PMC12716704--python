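"""Model and pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

VALID_VIEWS = ("spatial", "lr", "similarity")


@dataclass
class ModelConfig:
    """Hyper-parameters for graph construction, the encoder stack and training.

    Defaults follow the published configuration of the method: ``k_neighbors=5``
    nearest neighbours for every cell-level graph, ``k_genes=30`` genes per
    cell-specific regulatory block, 64-dimensional node2vec gene features, a
    shared 32-dimensional latent space encoded by two-layer GCNs, four
    attention heads, InfoNCE temperature ``tau=0.3``, contrastive margin
    ``margin=0.1`` weighted by ``lambda_margin=0.1``, total loss
    ``L_recon + 0.1*L_contrast + 0.1*L_align``, and up to 120 training epochs
    with early stopping.
    """

    k_neighbors: int = 5
    k_genes: int = 30
    latent_dim: int = 32
    hidden_dim: int = 128
    gene_embed_dim: int = 64
    heads: int = 4
    tau: float = 0.3
    margin: float = 0.1
    lambda_margin: float = 0.1
    n_hard: int = 5
    w_contrast: float = 0.1
    w_align: float = 0.1
    epochs: int = 120
    patience: int = 60
    learning_rate: float = 1e-3
    seed: int = 0
    # graph construction
    bandwidth_rank: int = 1          # neighbour rank defining the adaptive kernel bandwidth
    alpha: float = 0.05              # permutation-test significance level
    n_perm: int = 100
    pca_dim: int = 32
    r_min: float = 0.6               # |Pearson r| threshold of the default GRN provider
    snf_K: int = 20
    snf_t: int = 20
    # ablation switches
    use_attention: bool = True
    use_contrast: bool = True
    use_align: bool = True
    views_enabled: tuple[str, ...] = VALID_VIEWS

    def __post_init__(self) -> None:
        if self.latent_dim % self.heads != 0:
            raise ValueError(
                f"latent_dim ({self.latent_dim}) must be divisible by heads ({self.heads})"
            )
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("w_contrast", "w_align", "lambda_margin", "margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        self.views_enabled = tuple(self.views_enabled)
        bad = [v for v in self.views_enabled if v not in VALID_VIEWS]
        if bad:
            raise ValueError(f"unknown views {bad}; valid: {VALID_VIEWS}")
        if not self.views_enabled:
            raise ValueError("at least one view must be enabled")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["views_enabled"] = list(self.views_enabled)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
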