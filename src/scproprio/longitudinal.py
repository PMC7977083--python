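"""Developmental gene-gene correlation panels.

For a chosen gene subset (typically adult subtype markers), compute the
pairwise Pearson correlation of log(CPM+1) over all cells of each
developmental stage, and display every stage in the gene order given by
average-linkage hierarchical clustering of the mature ("adult")
reference stage. Correlations that are strong in the adult and fade at
earlier stages indicate that subtype co-expression programs assemble
late in development.

Natural log is the convention here (elsewhere the pipeline uses log10);
Pearson r is invariant to the log base, so the choice is cosmetic and
kept only for fidelity to the analysis this module reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .containers import NormalizedMatrix
from .modules import log_cpm


@dataclass
class CorrelationPanel:
    """Per-stage gene-gene correlation matrices in a common gene order."""

    stages: list[str]
    matrices: dict[str, pd.DataFrame]
    gene_order: list[str]
    reference_stage: str
    summary: pd.Series | None = None  # per-stage mean |r| over scoring gene pairs


def gene_correlation_matrix(
    norm: NormalizedMatrix, genes: list[str], log_base: float = np.e
) -> pd.DataFrame:
    """Pearson r of log(CPM+1) between every pair of the given genes.

    Zero-variance genes get r = 0 against everything (flagged by warning)
    and 1 on the diagonal, keeping the matrix well-formed.
    """
    if norm.n_cells < 3:
        raise ValueError("correlation needs at least 3 cells")
    if len(genes) < 2:
        raise ValueError("correlation needs at least 2 genes")
    gidx = norm.gene_index()
    missing = [g for g in genes if g not in gidx]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    X = log_cpm(norm.values[[gidx[g] for g in genes]], base=log_base)
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance gene(s) assigned r = 0: {[g for g, z in zip(genes, flat) if z]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=genes, columns=genes)


def reference_ordering(adult_matrix: pd.DataFrame) -> list[str]:
    """Dendrogram leaf order from average-linkage clustering on 1 - r.

    Deterministic: scipy's leaf ordering breaks ties by lower index first.
    """
    vals = adult_matrix.to_numpy()
    if vals.shape[0] != vals.shape[1] or not np.allclose(vals, vals.T, atol=1e-10):
        raise ValueError("reference correlation matrix must be square and symmetric")
    genes = list(adult_matrix.index)
    if len(genes) <= 2:
        return genes
    dist = 1.0 - (vals + vals.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(np.clip(dist, 0.0, None), checks=False), method="average")
    return [genes[i] for i in leaves_list(Z)]


def build_panel(
    datasets: dict[str, NormalizedMatrix],
    genes: list[str],
    reference_stage: str,
    stage_order: list[str] | None = None,
    scoring_groups: list[list[str]] | None = None,
    log_base: float = np.e,
) -> CorrelationPanel:
    """One correlation matrix per stage, ordered by the reference stage.

    Genes missing from any stage are dropped everywhere (with a warning
    naming them). ``scoring_groups`` (e.g. the planted or inferred marker
    modules) define the per-stage summary statistic: mean |r| over
    within-group gene pairs; without groups, all off-diagonal pairs score.
    """
    if reference_stage not in datasets:
        raise KeyError(f"reference stage {reference_stage!r} not among datasets")
    stages = stage_order or list(datasets)

    missing: set[str] = set()
    for stage, norm in datasets.items():
        gset = set(norm.gene_ids)
        missing |= {g for g in genes if g not in gset}
    if missing:
        warnings.warn(f"genes missing at some stage dropped everywhere: {sorted(missing)}")
    kept = [g for g in genes if g not in missing]
    if len(kept) < 2:
        raise ValueError("fewer than 2 genes shared across all stages")

    ref = gene_correlation_matrix(datasets[reference_stage], kept, log_base=log_base)
    order = reference_ordering(ref)

    matrices = {
        stage: gene_correlation_matrix(datasets[stage], kept, log_base=log_base).loc[order, order]
        for stage in stages
    }

    pair_mask = _pair_mask(order, scoring_groups)
    summary = pd.Series(
        {
            stage: float(np.abs(m.to_numpy())[pair_mask].mean())
            for stage, m in matrices.items()
        },
        name="mean_abs_within_module_r",
    )
    return CorrelationPanel(list(stages), matrices, order, reference_stage, summary)


def _pair_mask(order: list[str], groups: list[list[str]] | None) -> np.ndarray:
    n = len(order)
    pos = {g: i for i, g in enumerate(order)}
    mask = np.zeros((n, n), dtype=bool)
    if groups is None:
        mask = np.triu(np.ones((n, n), dtype=bool), 1)
    else:
        for group in groups:
            idx = [pos[g] for g in group if g in pos]
            for i, a in enumerate(idx):
                for b in idx[i + 1 :]:
                    mask[min(a, b), max(a, b)] = True
    return mask
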