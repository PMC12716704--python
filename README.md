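# magnet-cci

Reconstruction of single-cell-resolution **cell–cell interaction (CCI)
networks** from spatial transcriptomics, for computational biologists who
have a cells × genes expression matrix, per-cell coordinates, and a curated
ligand–receptor pair list, and want a scored interaction network between
individual cells rather than between cell types.

## The model

Tissue communication leaves several complementary traces: physical
proximity, ligand–receptor co-expression, transcriptional similarity, and
each cell's internal regulatory state. The package builds one graph per
trace:

| view | weight |
|---|---|
| spatial | `W_ij = exp(-d_ij² / 2σ_i²)`, σ_i = nearest-neighbour distance |
| ligand–receptor | `Σ_pairs E_l′(i)·E_r′(j)·exp(-d_ij²/2σ²)`, permutation-filtered (p < 0.05) |
| similarity | fuzzy union `p+q-pq` of `exp(-max(0, d_ij-ρ_i)/(σ_i+ε))` in PCA space |
| gene blocks | per-cell 30-gene regulatory networks, stacked block-diagonally |

Each view is encoded by a two-layer GCN into a shared 32-d space; gene-node
embeddings (64-d node2vec features) are pooled per cell by softmax
attention. Three cross-attention branches (4 heads) let each cell view
query the pooled gene representation; a learned gate combines the branches
into `Z_final`, and an inner-product decoder `Â_ij = σ(z_i·z_j)` predicts
interactions. Training minimizes

```
L = BCE(Â, A_target) + 0.1·(InfoNCE_τ=0.3 + 0.1·margin) + 0.1·‖Z - P(x̄)‖²
```

where `A_target` is a consensus adjacency obtained by Similarity Network
Fusion of the three cell-level views (supervision only, never an input).
Evaluation follows the edge-level link-prediction protocol: held-out
positive edges plus sampled non-edges, reporting AP / AUROC / AUPRC / F1.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a 150-cell, 3-cluster tissue with planted interface signalling,
train, and evaluate:

```python
from magnet import ModelConfig, SimulationSpec, simulate_dataset, make_toy_lr_db
from magnet.training import run_single

spec = SimulationSpec(seed=7)           # 150 cells, 60 genes, 3 clusters
ds, truth = simulate_dataset(spec)
report, history, model, split = run_single(
    ds, make_toy_lr_db(spec), ModelConfig(seed=7), r=0.3
)
print(f"test AP    {report.ap:.3f}")
print(f"test AUROC {report.auroc:.3f}")
```

prints

```
test AP    0.977
test AUROC 0.977
```

meaning that with 30% of the consensus edges held out, the model ranks a
held-out true interaction above a random non-interacting pair ~98% of the
time, and its precision–recall trade-off is near perfect on this planted
instance. The same flow is available from the shell:

```bash
magnet simulate --cells 150 --genes 60 --seed 7 --out data/
magnet run --config config.yaml --out run/        # full pipeline
magnet ablate --config config.yaml --out abl/     # module ablations
magnet analyze --run run/ --top-frac 0.05 --hub-degree 10 --out analysis/
```

`magnet run` writes `metrics.json`, a per-epoch `history.csv`, trained
parameters (`params.npz`), the scored edge list, and a manifest with input
digests so identical configs reproduce byte-identical metrics.

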