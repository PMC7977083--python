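"""Core in-memory containers shared across the pipeline.

All matrices are oriented genes x cells, matching the plate-seq count
tables the pipeline consumes. Identifiers are plain strings; per-cell
metadata (developmental stage, sequencing batch) travels with the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x cells.

    Parameters
    ----------
    values
        Nonnegative integer array of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique identifier lists matching the matrix dimensions.
    cell_meta
        Optional per-cell metadata (``stage``, ``batch``) indexed by cell id.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D (genes x cells)")
        if (self.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValueError("cell_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids are not unique")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, cell_ids: list[str]) -> "CountMatrix":
        idx = {c: j for j, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in cell_ids]
        return CountMatrix(
            self.values[:, cols],
            list(self.gene_ids),
            list(cell_ids),
            self.cell_meta.loc[cell_ids].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class NormalizedMatrix:
    """Counts-per-million matrix with the same identifiers as its source."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, cell_ids: list[str]) -> "NormalizedMatrix":
        idx = {c: j for j, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in cell_ids]
        return NormalizedMatrix(self.values[:, cols], list(self.gene_ids), list(cell_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class GeneModuleSet:
    """Co-expression gene modules with eigengene profiles.

    ``eigengenes`` has one unit-variance row per module, aligned with
    ``cell_ids``; sign is oriented so each eigengene correlates positively
    with its module's mean expression profile.
    """

    modules: list[list[str]]
    eigengenes: np.ndarray  # modules x cells
    cell_ids: list[str]
    significance_p: list[float] = field(default_factory=list)
    params: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.modules)


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels plus split/merge provenance.

    ``minor_flags`` marks clusters below the minor-cluster size threshold
    (final clusters comprising fewer than 15 cells are reported but, by
    default, omitted from marker analysis).
    """

    labels: pd.Series  # index cell id -> cluster id (str)
    tree: dict[str, Any]
    minor_flags: dict[str, bool] = field(default_factory=dict)
    minor_size_threshold: int = 15

    def __post_init__(self) -> None:
        sizes = self.labels.value_counts()
        self.minor_flags = {str(c): int(n) < self.minor_size_threshold for c, n in sizes.items()}

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def major_clusters(self) -> list[str]:
        return [c for c, minor in sorted(self.minor_flags.items()) if not minor]

    def n_clusters(self) -> int:
        return self.labels.nunique()


@dataclass
class CoClusterMatrix:
    """Pairwise co-clustering proportions from bootstrap runs.

    ``proportions[i, j]`` is the fraction of runs, among those that sampled
    both cells, in which cells i and j landed in the same cluster; pairs
    never co-sampled are NaN. ``cosample_counts`` records the denominator.
    """

    proportions: np.ndarray
    cosample_counts: np.ndarray
    cell_ids: list[str]
    n_iter: int
    subsample_frac: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.cell_ids, columns=self.cell_ids)
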