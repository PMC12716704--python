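"""Edge-split protocol, training loop, and link-prediction metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)

from magnet.autodiff import Adam
from magnet.config import ModelConfig
from magnet.data import LigandReceptorDB, SpatialDataset, normalize_expression
from magnet.embed import embed_gene_nodes
from magnet.graphs import (
    GeneBlockGraph,
    TargetAdjacency,
    ViewGraph,
    build_lr_graph,
    build_similarity_graph,
    build_spatial_graph,
    infer_cell_grns,
    select_genes_per_cell,
)
from magnet.losses import (
    ContrastiveConfig,
    center_alignment_loss,
    contrastive_loss,
    decode_adjacency,
    reconstruction_loss,
    total_loss,
)
from magnet.model import MagnetModel
from magnet.snf import build_target

logger = logging.getLogger(__name__)


@dataclass
class EdgeSplit:
    """Disjoint train/val/test positive edges with matched sampled negatives."""

    train_pos: np.ndarray
    val_pos: np.ndarray
    test_pos: np.ndarray
    train_neg: np.ndarray
    val_neg: np.ndarray
    test_neg: np.ndarray
    r: float = 0.0
    seed: int = 0

    def digest(self) -> int:
        """Order-independent hash of the full split, for audit."""
        parts = [
            self.train_pos, self.val_pos, self.test_pos,
            self.train_neg, self.val_neg, self.test_neg,
        ]
        h = 0
        for a in parts:
            h = hash((h, a.tobytes(), a.shape)) & 0x7FFFFFFF
        return h


@dataclass
class TrainHistory:
    total: list[float] = field(default_factory=list)
    recon: list[float] = field(default_factory=list)
    contrast: list[float] = field(default_factory=list)
    align: list[float] = field(default_factory=list)
    val_ap: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class MetricsReport:
    ap: float
    auroc: float
    auprc: float
    f1: float
    precision: float
    recall: float
    ap_sd: float = 0.0
    auroc_sd: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "AP": self.ap, "AUROC": self.auroc, "AUPRC": self.auprc,
            "F1": self.f1, "precision": self.precision, "recall": self.recall,
            "AP_sd": self.ap_sd, "AUROC_sd": self.auroc_sd,
        }


def split_edges(
    target: TargetAdjacency,
    r: float,
    val_fraction: float = 0.15,
    seed: int = 0,
) -> EdgeSplit:
    """Hold out a fraction ``r`` of positive edges for testing.

    Unique undirected positives (i < j) are enumerated; ``round(r * E)``
    (banker's rounding) go to test, ``round(val_fraction * remainder)`` to
    validation, the rest to training. One negative (a uniformly sampled
    non-edge) is drawn per positive, without replacement and disjoint
    across partitions.
    """
    if not (0 < r < 1):
        raise ValueError("r must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pos = target.positive_edges()
    E = len(pos)
    n_test = round(r * E)
    n_val = round(val_fraction * (E - n_test))
    n_train = E - n_test - n_val
    if n_train < 1:
        raise ValueError(f"r={r} leaves no training edges (E={E})")
    perm = rng.permutation(E)
    test_pos = pos[perm[:n_test]]
    val_pos = pos[perm[n_test : n_test + n_val]]
    train_pos = pos[perm[n_test + n_val :]]

    n = target.A_target.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    nonedge_mask = target.A_target[iu, ju] == 0
    nonedges = np.c_[iu[nonedge_mask], ju[nonedge_mask]]
    if len(nonedges) < E:
        raise ValueError("not enough non-edges to sample negatives")
    sel = rng.choice(len(nonedges), size=E, replace=False)
    neg = nonedges[sel]
    test_neg = neg[:n_test]
    val_neg = neg[n_test : n_test + n_val]
    train_neg = neg[n_test + n_val :]
    return EdgeSplit(
        train_pos=train_pos, val_pos=val_pos, test_pos=test_pos,
        train_neg=train_neg, val_neg=val_neg, test_neg=test_neg,
        r=r, seed=seed,
    )


def _edge_scores(A_hat: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    edges = np.vstack([pos, neg])
    y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
    s = A_hat[edges[:, 0], edges[:, 1]]
    return y, s


def evaluate(
    A_hat: np.ndarray, pos: np.ndarray, neg: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Link-prediction metrics over a positive/negative edge partition."""
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("evaluation needs both classes present")
    y, s = _edge_scores(A_hat, pos, neg)
    ap = float(average_precision_score(y, s))
    auroc = float(roc_auc_score(y, s))
    prec_c, rec_c, _ = precision_recall_curve(y, s)
    auprc = float(auc(rec_c, prec_c))
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsReport(ap=ap, auroc=auroc, auprc=auprc, f1=f1,
                         precision=precision, recall=recall)


# ---------------------------------------------------------------------------
# Pipeline assembly


@dataclass
class BuiltGraphs:
    views: dict[str, ViewGraph]
    gene_graph: GeneBlockGraph
    X_g: np.ndarray
    target: TargetAdjacency
    X_c: np.ndarray          # model input: library-size/log1p then per-gene z-score
    X_c_anchor: np.ndarray   # uncentered log-normalized expression (alignment anchor)


def build_all(
    ds: SpatialDataset, lr_db: LigandReceptorDB, cfg: ModelConfig
) -> BuiltGraphs:
    """Construct every graph, the gene features, and the supervision target."""
    spatial = build_spatial_graph(ds, cfg)
    lr = build_lr_graph(ds, lr_db, cfg)
    sim = build_similarity_graph(ds, cfg)
    k_genes = min(cfg.k_genes, ds.n_genes)
    gene_map = select_genes_per_cell(ds, lr_db, k_genes)
    gene_graph = infer_cell_grns(
        ds, gene_map, provider="default_corr", lr_db=lr_db,
        r_min=cfg.r_min, n_neighbors=cfg.k_neighbors,
    )
    X_g = embed_gene_nodes(gene_graph.A_g, d=cfg.gene_embed_dim, seed=cfg.seed)
    target = build_target(ds, spatial.W, lr.W, sim.W, cfg)
    X_log = normalize_expression(ds.expr, "library_size_log1p")
    X_c = normalize_expression(X_log, "zscore_per_gene")
    return BuiltGraphs(
        views={"spatial": spatial, "lr": lr, "similarity": sim},
        gene_graph=gene_graph, X_g=X_g, target=target,
        X_c=X_c, X_c_anchor=X_log,
    )


def train(
    built: BuiltGraphs, split: EdgeSplit, cfg: ModelConfig
) -> tuple[MagnetModel, TrainHistory]:
    """Full-batch end-to-end training with early stopping on validation AP.

    Test edges never enter the gradient: supervision uses only training
    positives plus their sampled negatives. The parameters of the best
    validation epoch are restored before returning.
    """
    model = MagnetModel(built.views, built.gene_graph, built.X_c, built.X_g, cfg)
    opt = Adam(model.params, lr=cfg.learning_rate)
    ccfg = ContrastiveConfig(
        tau=cfg.tau, margin=cfg.margin,
        lambda_margin=cfg.lambda_margin, n_hard=cfg.n_hard,
    )
    hist = TrainHistory()
    best_ap, best_params, since_best = -np.inf, None, 0
    use_val = len(split.val_pos) > 0 and len(split.val_neg) > 0
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        Z_views, Zg_pooled, Z_final = model.forward()
        recon = reconstruction_loss(
            Z_final, built.target.A_target, split.train_pos, split.train_neg
        )
        contrast = (
            contrastive_loss(Z_views, Zg_pooled, ccfg) if cfg.use_contrast else 0.0
        )
        align = (
            center_alignment_loss(Z_final, built.X_c_anchor, model.params["align_P"])
            if cfg.use_align
            else 0.0
        )
        loss = total_loss(recon, contrast, align, cfg.w_contrast, cfg.w_align)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={float(loss.data)}"
            )
        loss.backward()
        opt.step()

        hist.total.append(float(loss.data))
        hist.recon.append(float(recon.data))
        hist.contrast.append(float(contrast.data) if cfg.use_contrast else 0.0)
        hist.align.append(float(align.data) if cfg.use_align else 0.0)

        A_hat = decode_adjacency(Z_final.data)
        if use_val:
            y, s = _edge_scores(A_hat, split.val_pos, split.val_neg)
            val_ap = float(average_precision_score(y, s))
        else:
            y, s = _edge_scores(A_hat, split.train_pos, split.train_neg)
            val_ap = float(average_precision_score(y, s))
        hist.val_ap.append(val_ap)
        if val_ap >= best_ap:
            # ties go to the later epoch: among equally validating models,
            # prefer the most-trained one
            best_params = {k: p.data.copy() for k, p in model.params.items()}
            hist.best_epoch = epoch
        if val_ap > best_ap + 1e-12:
            best_ap = val_ap
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, hist.best_epoch)
                break
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
    return model, hist


def predict_adjacency(model: MagnetModel) -> np.ndarray:
    _, _, Z_final = model.forward()
    return decode_adjacency(Z_final.data)


def run_single(
    ds: SpatialDataset,
    lr_db: LigandReceptorDB,
    cfg: ModelConfig,
    r: float = 0.3,
    val_fraction: float = 0.15,
) -> tuple[MetricsReport, TrainHistory, MagnetModel, EdgeSplit]:
    """Build graphs, split edges, train, and evaluate on the test partition."""
    built = build_all(ds, lr_db, cfg)
    split = split_edges(built.target, r=r, val_fraction=val_fraction, seed=cfg.seed)
    model, hist = train(built, split, cfg)
    A_hat = predict_adjacency(model)
    report = evaluate(A_hat, split.test_pos, split.test_neg)
    return report, hist, model, split


def run_replicates(
    ds: SpatialDataset,
    lr_db: LigandReceptorDB,
    cfg: ModelConfig,
    seeds: list[int],
    r: float = 0.3,
) -> MetricsReport:
    """Rerun the pipeline per seed (split + init differ) and aggregate."""
    if len(seeds) < 2:
        raise ValueError("need >= 2 seeds for a standard deviation")
    reports = []
    for s in seeds:
        scfg = ModelConfig.from_dict({**cfg.to_dict(), "seed": int(s)})
        rep, *_ = run_single(ds, lr_db, scfg, r=r)
        reports.append(rep)
    aps = np.array([r_.ap for r_ in reports])
    rocs = np.array([r_.auroc for r_ in reports])
    return MetricsReport(
        ap=float(aps.mean()),
        auroc=float(rocs.mean()),
        auprc=float(np.mean([r_.auprc for r_ in reports])),
        f1=float(np.mean([r_.f1 for r_ in reports])),
        precision=float(np.mean([r_.precision for r_ in reports])),
        recall=float(np.mean([r_.recall for r_ in reports])),
        ap_sd=float(aps.std(ddof=0)),
        auroc_sd=float(rocs.std(ddof=0)),
    )
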