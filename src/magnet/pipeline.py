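"""Run orchestration: configuration, manifests, end-to-end pipeline, ablations."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from magnet.config import ModelConfig
from magnet.data import (
    LigandReceptorDB,
    SpatialDataset,
    read_dataset,
    read_lr_db,
    write_dataset,
    write_lr_db,
)
from magnet.analysis import (
    find_hubs,
    intra_inter_distance_test,
    threshold_top_edges,
    topology_stats,
)
from magnet.nn import save_params
from magnet.simulate import SimulationSpec, make_toy_lr_db, simulate_dataset
from magnet.training import run_single

logger = logging.getLogger(__name__)


def file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict[str, Any]
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    version: str = ""
    started: str = ""

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _load_inputs(io_cfg: dict[str, Any], out_dir: str, seed: int):
    """Resolve inputs: simulate a fixture or read user files."""
    if io_cfg.get("simulate", False):
        sim_kwargs = {
            k: v for k, v in io_cfg.items()
            if k in SimulationSpec.__dataclass_fields__
        }
        sim_kwargs.setdefault("seed", seed)
        spec = SimulationSpec(**sim_kwargs)
        ds, truth = simulate_dataset(spec)
        lr_db = make_toy_lr_db(spec)
        sim_dir = os.path.join(out_dir, "inputs")
        paths = write_dataset(ds, sim_dir)
        write_lr_db(lr_db, os.path.join(sim_dir, "lr_pairs.tsv"))
        with open(os.path.join(sim_dir, "truth_edges.tsv"), "w") as fh:
            fh.write("src\tdst\n")
            for i, j in sorted(truth.edges):
                fh.write(f"{i}\t{j}\n")
        return ds, lr_db, paths
    expr = io_cfg["expr"]
    coords = io_cfg["coords"]
    fmt = io_cfg.get("format", "mtx" if expr.endswith(".mtx") else "csv")
    for p in (expr, coords, io_cfg["lr_pairs"]):
        if not os.path.exists(p):
            raise FileNotFoundError(f"input file not found: {p}")
    ds = read_dataset(expr, coords, format=fmt)
    lr_db = read_lr_db(io_cfg["lr_pairs"])
    return ds, lr_db, {"expr": expr, "coords": coords, "lr_pairs": io_cfg["lr_pairs"]}


def run_pipeline(config: dict[str, Any] | str, out_dir: str | None = None) -> str:
    """Execute simulate/ingest -> build-graphs -> train -> evaluate -> analyze.

    ``config`` is a YAML path or an already-parsed dict with optional
    sections ``io``, ``model``, ``evaluation``, ``analysis``. Every artifact
    lands under one run directory together with a manifest recording the
    config snapshot and input digests.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    io_cfg = dict(config.get("io", {}))
    model_cfg = ModelConfig.from_dict(config.get("model", {}))
    eval_cfg = dict(config.get("evaluation", {}))
    ana_cfg = dict(config.get("analysis", {}))
    out_dir = out_dir or config.get("out_dir", "magnet_run")
    os.makedirs(out_dir, exist_ok=True)

    t0 = time.time()
    ds, lr_db, input_paths = _load_inputs(io_cfg, out_dir, model_cfg.seed)
    from magnet import __version__

    manifest = RunManifest(
        config={k: v for k, v in config.items() if k != "out_dir"},
        seed=model_cfg.seed,
        input_digests={k: file_digest(p) for k, p in input_paths.items()},
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(os.path.join(out_dir, "manifest.json"))
    logger.info("inputs ready in %.1fs (N=%d, G=%d)", time.time() - t0, ds.n_cells, ds.n_genes)

    t1 = time.time()
    r = float(eval_cfg.get("split", 0.3))
    report, hist, model, split = run_single(ds, lr_db, model_cfg, r=r)
    logger.info("training done in %.1fs", time.time() - t1)

    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
    pd.DataFrame(
        {
            "epoch": np.arange(len(hist.total)),
            "total": hist.total, "recon": hist.recon,
            "contrast": hist.contrast, "align": hist.align,
            "val_ap": hist.val_ap,
        }
    ).to_csv(os.path.join(out_dir, "history.csv"), index=False)
    save_params(model.params, os.path.join(out_dir, "params.npz"))

    from magnet.training import predict_adjacency

    A_hat = predict_adjacency(model)
    frac = float(ana_cfg.get("top_fraction", 0.05))
    net = threshold_top_edges(A_hat, frac, coords=ds.coords, labels=ds.labels)
    pd.DataFrame(
        {"src": net.edges[:, 0], "dst": net.edges[:, 1], "score": net.scores}
    ).to_csv(os.path.join(out_dir, "predicted_edges.tsv"), sep="\t", index=False)

    analysis: dict[str, Any] = {"top_fraction": frac, "n_edges": int(len(net.edges))}
    degree, closeness = topology_stats(net)
    hubs = find_hubs(net, int(ana_cfg.get("hub_degree", 10)))
    analysis["n_hubs"] = len(hubs)
    analysis["mean_degree"] = float(degree.mean())
    analysis["mean_closeness"] = float(closeness.mean())
    if ds.labels is not None:
        try:
            ks, p, intra, inter = intra_inter_distance_test(net, ds.labels)
            analysis.update(
                ks_statistic=ks, ks_pvalue=p,
                intra_mean_distance=float(np.mean(intra)),
                inter_mean_distance=float(np.mean(inter)),
            )
        except ValueError as exc:
            analysis["ks_note"] = str(exc)
    with open(os.path.join(out_dir, "analysis.json"), "w") as fh:
        json.dump(analysis, fh, indent=2, sort_keys=True)
    return out_dir


STANDARD_VARIANTS = {
    "full": {},
    "no_attention": {"use_attention": False},
    "no_contrast": {"use_contrast": False},
    "no_align": {"use_align": False},
}

GRAPH_SUBSET_VARIANTS = {
    "spatial_only": {"views_enabled": ["spatial"]},
    "spatial_lr": {"views_enabled": ["spatial", "lr"]},
    "spatial_similarity": {"views_enabled": ["spatial", "similarity"]},
    "lr_similarity": {"views_enabled": ["lr", "similarity"]},
    "all_views": {"views_enabled": ["spatial", "lr", "similarity"]},
}


def ablation_matrix(
    ds: SpatialDataset,
    lr_db: LigandReceptorDB,
    base_cfg: ModelConfig,
    variants: dict[str, dict[str, Any]] | None = None,
    r: float = 0.3,
    seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Run each config variant with shared seeds/splits; one metrics row each.

    All variants of a given seed share the identical edge split (the split
    depends only on the built target and the seed), so differences isolate
    the architectural change.
    """
    from magnet.training import (
        build_all,
        evaluate,
        predict_adjacency,
        split_edges,
        train,
    )

    variants = variants if variants is not None else STANDARD_VARIANTS
    seeds = seeds or [base_cfg.seed]
    prepared = []
    for s in seeds:
        cfg_s = ModelConfig.from_dict({**base_cfg.to_dict(), "seed": int(s)})
        built = build_all(ds, lr_db, cfg_s)
        split = split_edges(built.target, r=r, seed=int(s))
        prepared.append((int(s), built, split))
    rows = []
    for name, overrides in variants.items():
        aps, rocs, digests = [], [], []
        for s, built, split in prepared:
            cfg = ModelConfig.from_dict(
                {**base_cfg.to_dict(), **overrides, "seed": s}
            )
            model, _ = train(built, split, cfg)
            rep = evaluate(predict_adjacency(model), split.test_pos, split.test_neg)
            aps.append(rep.ap)
            rocs.append(rep.auroc)
            digests.append(split.digest())
        rows.append(
            {
                "variant": name, "AP": float(np.mean(aps)),
                "AP_sd": float(np.std(aps)), "AUROC": float(np.mean(rocs)),
                "split_digests": tuple(digests),
            }
        )
    return pd.DataFrame(rows)
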