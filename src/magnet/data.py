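"""Domain types, file IO and expression normalization.

Expression comes in either as a dense CSV/TSV (cells as rows, header row of
gene names) or as a MatrixMarket sparse matrix with ``.rows`` / ``.cols``
sidecar text files carrying cell ids and gene names. Coordinates are a CSV
with ``x,y`` columns (optional ``cell_id``), row-aligned with the expression
matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class DataError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class SpatialDataset:
    """A spatially resolved expression experiment.

    Attributes
    ----------
    expr : (N, G) float array
        Nonnegative expression values, one row per cell.
    coords : (N, 2) float array
        Spatial x/y positions, row-aligned with ``expr``.
    gene_names : list of str
        Unique gene symbols, one per expression column.
    cell_ids : list of str
        Unique cell identifiers.
    labels : list of str, optional
        Cluster or annotation labels per cell.
    """

    expr: np.ndarray
    coords: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.expr.shape
        if n < 2 or g < 2:
            raise DataError(f"need at least 2 cells and 2 genes, got {n} x {g}")
        if self.coords.shape != (n, 2):
            raise DataError(
                f"coords shape {self.coords.shape} does not match {n} cells x 2"
            )
        if not np.all(np.isfinite(self.expr)):
            raise DataError("expression contains NaN or Inf")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("coordinates contain NaN or Inf")
        if len(self.gene_names) != g:
            raise DataError(f"{len(self.gene_names)} gene names for {g} columns")
        if len(set(self.gene_names)) != g:
            raise DataError("gene names are not unique")
        if len(self.cell_ids) != n:
            raise DataError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(set(self.cell_ids)) != n:
            raise DataError("cell ids are not unique")
        if self.labels is not None and len(self.labels) != n:
            raise DataError(f"{len(self.labels)} labels for {n} cells")

    @property
    def n_cells(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"gene {name!r} not in dataset") from None


@dataclass
class LigandReceptorDB:
    """Curated ligand-receptor gene pairs (order preserved, deduplicated)."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        clean: list[tuple[str, str]] = []
        for lig, rec in self.pairs:
            lig, rec = str(lig).strip(), str(rec).strip()
            if not lig or not rec:
                raise DataError("empty ligand or receptor symbol")
            if (lig, rec) in seen:
                continue
            seen.add((lig, rec))
            clean.append((lig, rec))
        self.pairs = clean

    def __len__(self) -> int:
        return len(self.pairs)

    def mappable_pairs(self, ds: SpatialDataset) -> list[tuple[int, int]]:
        """Index pairs (ligand col, receptor col) restricted to dataset genes."""
        idx = {g: i for i, g in enumerate(ds.gene_names)}
        return [
            (idx[lig], idx[rec])
            for lig, rec in self.pairs
            if lig in idx and rec in idx
        ]


# ---------------------------------------------------------------------------
# IO


def _read_coords(coords_path: str) -> tuple[np.ndarray, list[str] | None]:
    df = pd.read_csv(coords_path)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise DataError(
            f"coordinate file must have x,y columns; found {list(df.columns)}"
        )
    xy = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    ids = df[cols["cell_id"]].astype(str).tolist() if "cell_id" in cols else None
    return xy, ids


def read_dataset(expr_path: str, coords_path: str, format: str = "csv") -> SpatialDataset:
    """Read expression + coordinates into a validated :class:`SpatialDataset`.

    ``format='csv'`` expects a dense table (cells x genes, gene-name header,
    optional leading cell-id column detected by a non-numeric first column).
    ``format='mtx'`` expects a MatrixMarket file alongside ``<expr>.rows`` and
    ``<expr>.cols`` sidecars listing cell ids and gene names.
    Expression is left untransformed; normalization is a separate step.
    """
    if format == "csv":
        sep = "\t" if expr_path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(expr_path, sep=sep)
        first = df.columns[0]
        if df[first].dtype == object:
            cell_ids = df[first].astype(str).tolist()
            df = df.drop(columns=[first])
        else:
            cell_ids = [f"cell{i}" for i in range(len(df))]
        try:
            expr = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            bad = df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
            row = int(np.argmax(bad.to_numpy())) if bad.any() else -1
            raise DataError(f"non-numeric expression value near row {row}: {exc}") from exc
        gene_names = [str(c) for c in df.columns]
    elif format == "mtx":
        mat = mmread(expr_path)
        expr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        rows_path, cols_path = expr_path + ".rows", expr_path + ".cols"
        if not (os.path.exists(rows_path) and os.path.exists(cols_path)):
            raise DataError(f"missing sidecar files {rows_path} / {cols_path}")
        cell_ids = [l.strip() for l in open(rows_path) if l.strip()]
        gene_names = [l.strip() for l in open(cols_path) if l.strip()]
    else:
        raise DataError(f"unknown format {format!r}; use 'csv' or 'mtx'")

    coords, coord_ids = _read_coords(coords_path)
    if coords.shape[0] != expr.shape[0]:
        raise DataError(
            f"expression has {expr.shape[0]} cells but coordinates have "
            f"{coords.shape[0]} rows"
        )
    if coord_ids is not None and coord_ids != cell_ids:
        # positional alignment is the contract; ids, when present, must agree
        raise DataError("cell_id column of coordinates disagrees with expression rows")
    return SpatialDataset(expr=expr, coords=coords, gene_names=gene_names, cell_ids=cell_ids)


def write_dataset(ds: SpatialDataset, out_dir: str, format: str = "csv") -> dict[str, str]:
    """Write a dataset to ``out_dir``; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    if format == "csv":
        expr_path = os.path.join(out_dir, "expression.csv")
        df = pd.DataFrame(ds.expr, columns=ds.gene_names)
        df.insert(0, "cell_id", ds.cell_ids)
        df.to_csv(expr_path, index=False, float_format="%.17g")
        paths["expr"] = expr_path
    elif format == "mtx":
        expr_path = os.path.join(out_dir, "expression.mtx")
        mmwrite(expr_path, coo_matrix(ds.expr))
        with open(expr_path + ".rows", "w") as fh:
            fh.write("\n".join(ds.cell_ids) + "\n")
        with open(expr_path + ".cols", "w") as fh:
            fh.write("\n".join(ds.gene_names) + "\n")
        paths["expr"] = expr_path
    else:
        raise DataError(f"unknown format {format!r}")
    coords_path = os.path.join(out_dir, "coords.csv")
    cdf = pd.DataFrame({"cell_id": ds.cell_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]})
    cdf.to_csv(coords_path, index=False, float_format="%.17g")
    paths["coords"] = coords_path
    if ds.labels is not None:
        labels_path = os.path.join(out_dir, "labels.csv")
        pd.DataFrame({"cell_id": ds.cell_ids, "label": ds.labels}).to_csv(labels_path, index=False)
        paths["labels"] = labels_path
    return paths


def read_lr_db(path: str) -> LigandReceptorDB:
    """Read a TSV ligand-receptor table with ``ligand`` and ``receptor`` columns."""
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in df.columns}
    if "ligand" not in lower or "receptor" not in lower:
        raise DataError(
            f"LR table needs 'ligand' and 'receptor' columns; found {list(df.columns)}"
        )
    pairs = list(zip(df[lower["ligand"]].astype(str), df[lower["receptor"]].astype(str)))
    return LigandReceptorDB(pairs=pairs)


def write_lr_db(db: LigandReceptorDB, path: str) -> None:
    pd.DataFrame(db.pairs, columns=["ligand", "receptor"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization


def normalize_expression(expr: np.ndarray, mode: str = "library_size_log1p") -> np.ndarray:
    """Normalize a cells x genes expression matrix.

    Modes
    -----
    ``library_size_log1p``
        Scale each cell to the median library size, then log1p. The default
        preprocessing for the model input feature matrix.
    ``minmax_per_gene``
        Map each gene column to [0, 1]; constant columns map to all zeros.
        Used for ligand-receptor score computation.
    ``zscore_per_gene``
        Center/scale each column to mean 0, sd 1; constant columns map to
        zeros.
    """
    expr = np.asarray(expr, dtype=float)
    if mode == "library_size_log1p":
        if np.any(expr < 0):
            raise DataError("library-size normalization requires nonnegative input")
        lib = expr.sum(axis=1, keepdims=True)
        target = np.median(lib[lib > 0]) if np.any(lib > 0) else 1.0
        scaled = np.where(lib > 0, expr / np.maximum(lib, 1e-300) * target, 0.0)
        return np.log1p(scaled)
    if mode == "minmax_per_gene":
        lo = expr.min(axis=0, keepdims=True)
        hi = expr.max(axis=0, keepdims=True)
        rng = hi - lo
        out = np.zeros_like(expr)
        nz = rng[0] > 0
        out[:, nz] = (expr[:, nz] - lo[0, nz]) / rng[0, nz]
        return out
    if mode == "zscore_per_gene":
        mu = expr.mean(axis=0, keepdims=True)
        sd = expr.std(axis=0, keepdims=True)
        out = np.zeros_like(expr)
        nz = sd[0] > 0
        out[:, nz] = (expr[:, nz] - mu[0, nz]) / sd[0, nz]
        return out
    raise DataError(f"unknown normalization mode {mode!r}")
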