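"""Reading and writing the pipeline's on-disk formats.

Count matrices travel either as MatrixMarket (``matrix.mtx`` with
``genes.tsv``/``cells.tsv`` sidecars; 1-based coordinates per the MTX
standard, converted at this boundary only) or as a dense CSV (genes as
rows). Planted truth and provenance are JSON; gene sets are GMT plus an
optional two-column child/parent TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .containers import CountMatrix
from .enrich import GeneSetCollection
from .synthetic import PlantedTruth

MTX_NAME = "matrix.mtx"
GENES_NAME = "genes.tsv"
CELLS_NAME = "cells.tsv"
CSV_NAME = "counts.csv"


def write_counts(counts: CountMatrix, path: str | Path, dialect: str = "mtx") -> Path:
    """Write a count matrix; ``dialect`` is 'mtx' (directory) or 'csv' (file)."""
    path = Path(path)
    if dialect == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sio.mmwrite(path / MTX_NAME, sparse.coo_matrix(counts.values))
        pd.Series(counts.gene_ids).to_csv(path / GENES_NAME, sep="\t", index=False, header=False)
        meta = counts.cell_meta.copy()
        meta.insert(0, "cell_id", counts.cell_ids)
        meta.to_csv(path / CELLS_NAME, sep="\t", index=False)
        return path
    if dialect == "csv":
        if path.suffix != ".csv":
            path = path / CSV_NAME
        path.parent.mkdir(parents=True, exist_ok=True)
        counts.to_frame().to_csv(path)
        return path
    raise ValueError(f"unknown dialect {dialect!r} (expected 'mtx' or 'csv')")


def read_counts(path: str | Path, dialect: str = "mtx") -> CountMatrix:
    """Read a count matrix written by :func:`write_counts` (lossless round trip)."""
    path = Path(path)
    if dialect == "mtx":
        mtx = path / MTX_NAME if path.is_dir() else path
        genes_f = mtx.parent / GENES_NAME
        cells_f = mtx.parent / CELLS_NAME
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise FileNotFoundError(f"missing required file: {f}")
        values = np.asarray(sio.mmread(mtx).todense()).astype(np.int64)
        gene_ids = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cells_f, sep="\t")
        cell_ids = cells["cell_id"].astype(str).tolist()
        if values.shape[0] != len(gene_ids):
            raise ValueError(f"gene sidecar {genes_f} has {len(gene_ids)} rows, matrix has {values.shape[0]}")
        if values.shape[1] != len(cell_ids):
            raise ValueError(f"cell sidecar {cells_f} has {len(cell_ids)} rows, matrix has {values.shape[1]}")
        meta = cells.set_index("cell_id")
        return CountMatrix(values, gene_ids, cell_ids, meta)
    if dialect == "csv":
        f = path / CSV_NAME if path.is_dir() else path
        df = pd.read_csv(f, index_col=0)
        return CountMatrix(
            df.to_numpy().astype(np.int64),
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
        )
    raise ValueError(f"unknown dialect {dialect!r} (expected 'mtx' or 'csv')")


def write_truth(truth: PlantedTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth.to_dict(), indent=2))
    return path


def read_truth(path: str | Path) -> PlantedTruth:
    return PlantedTruth.from_dict(json.loads(Path(path).read_text()))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes (tab-separated)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, genes): {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = ".") -> Path:
    path = Path(path)
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_parent_table(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (child, parent) -> child -> parent-list mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], comment="#")
    out: dict[str, list[str]] = {}
    for child, parent in zip(df["child"].astype(str), df["parent"].astype(str)):
        out.setdefault(child, []).append(parent)
    return out


def load_gene_sets(
    gmt_path: str | Path,
    universe: list[str],
    parent_path: str | Path | None = None,
) -> GeneSetCollection:
    sets = read_gmt(gmt_path)
    parents = read_parent_table(parent_path) if parent_path else {}
    return GeneSetCollection(sets=sets, universe=list(universe), parents=parents)
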