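"""Cell-level quality control and CPM normalization.

Two quality rules are applied, in a fixed order: (1) gene detection —
cells detecting fewer than ``min_genes`` (default 2000) genes are
removed; (2) satellite-cell contamination, for which two published
dialects exist and both are implemented:

* ``methods`` (default): keep a cell iff Mbp CPM < 10,000 AND
  Apoe CPM < 20 (fully specified thresholds).
* ``main_text``: remove a cell if its summed raw Apoe+Mpz count exceeds
  10% of the dataset-mean summed Apoe+Mpz count.

The dialects are not equivalent; the choice is a config option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix

log = logging.getLogger(__name__)

DEFAULT_CONTAMINANT_GENES = ("Apoe", "Mpz", "Mbp")
MIN_GENES_DEFAULT = 2000
MBP_CPM_MAX = 10_000.0
APOE_CPM_MAX = 20.0
MAIN_TEXT_FRACTION = 0.10


@dataclass
class CellQCReport:
    """Per-cell QC metrics with pass flags under both contamination dialects."""

    table: pd.DataFrame  # index: cell id
    contaminant_genes: tuple[str, ...] = DEFAULT_CONTAMINANT_GENES
    dialect: str = "methods"
    min_genes: int = MIN_GENES_DEFAULT

    @property
    def pass_genes(self) -> pd.Series:
        return self.table["pass_genes"]

    @property
    def pass_contamination(self) -> pd.Series:
        col = "pass_contamination_methods" if self.dialect == "methods" else "pass_contamination_main_text"
        return self.table[col]


def cpm_normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Counts-per-million: each count divided by the cell total, times 1e6.

    Cells with zero total count become all-zero columns (warned, not fatal).
    """
    totals = counts.values.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        ids = [c for c, z in zip(counts.cell_ids, zero) if z]
        warnings.warn(f"{zero.sum()} cell(s) with zero total count left as all-zero columns: {ids}")
    safe = np.where(zero, 1.0, totals)
    cpm = counts.values / safe * 1e6
    return NormalizedMatrix(cpm, list(counts.gene_ids), list(counts.cell_ids))


def qc_metrics(
    counts: CountMatrix,
    contaminant_genes: tuple[str, ...] = DEFAULT_CONTAMINANT_GENES,
    min_genes: int = MIN_GENES_DEFAULT,
    dialect: str = "methods",
) -> CellQCReport:
    """Compute per-cell QC metrics and pass flags under both dialects.

    Contaminant genes absent from the matrix are warned about and treated
    as all-zero.
    """
    if dialect not in ("methods", "main_text"):
        raise ValueError(f"unknown contamination dialect: {dialect!r}")
    gidx = counts.gene_index()
    missing = [g for g in contaminant_genes if g not in gidx]
    if missing:
        warnings.warn(f"contaminant gene(s) not in matrix, treated as zero: {missing}")

    values = counts.values
    totals = values.sum(axis=0).astype(float)
    genes_detected = (values > 0).sum(axis=0)

    def gene_row(g: str) -> np.ndarray:
        return values[gidx[g]].astype(float) if g in gidx else np.zeros(counts.n_cells)

    safe = np.where(totals == 0, 1.0, totals)
    cont_cpm = {g: gene_row(g) / safe * 1e6 for g in contaminant_genes}

    # Methods dialect: per-gene CPM ceilings (Mbp < 10,000; Apoe < 20).
    pass_methods = np.ones(counts.n_cells, dtype=bool)
    if "Mbp" in contaminant_genes:
        pass_methods &= cont_cpm["Mbp"] < MBP_CPM_MAX
    if "Apoe" in contaminant_genes:
        pass_methods &= cont_cpm["Apoe"] < APOE_CPM_MAX

    # Main-text dialect: summed Apoe+Mpz raw counts vs 10% of the dataset mean.
    main_genes = [g for g in ("Apoe", "Mpz") if g in contaminant_genes]
    summed = sum((gene_row(g) for g in main_genes), start=np.zeros(counts.n_cells))
    mean_summed = float(summed.mean()) if counts.n_cells else 0.0
    pass_main = summed <= MAIN_TEXT_FRACTION * mean_summed

    table = pd.DataFrame(
        {
            "genes_detected": genes_detected,
            "total_umi": values.sum(axis=0),
            **{f"{g}_cpm": cont_cpm[g] for g in contaminant_genes},
            "pass_genes": (genes_detected >= min_genes) & (totals > 0),
            "pass_contamination_methods": pass_methods,
            "pass_contamination_main_text": pass_main,
        },
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )
    return CellQCReport(table, tuple(contaminant_genes), dialect, min_genes)


def filter_cells(
    counts: CountMatrix, report: CellQCReport
) -> tuple[CountMatrix, dict[str, list[str]]]:
    """Apply the QC rules in fixed order: gene detection, then contamination.

    The contamination rule is evaluated only on cells surviving the
    detection rule, so the removal counts are order-dependent and
    reproducible.
    """
    if list(report.table.index) != list(counts.cell_ids):
        raise ValueError("QC report does not match the count matrix's cells")
    pass_genes = report.pass_genes.to_numpy()
    pass_cont = report.pass_contamination.to_numpy()

    lowdepth = [c for c, ok in zip(counts.cell_ids, pass_genes) if not ok]
    contaminated = [
        c
        for c, g_ok, c_ok in zip(counts.cell_ids, pass_genes, pass_cont)
        if g_ok and not c_ok
    ]
    kept = [c for c, g_ok, c_ok in zip(counts.cell_ids, pass_genes, pass_cont) if g_ok and c_ok]
    if not kept:
        raise ValueError("no cells survive QC")
    log.info(
        "QC kept %d/%d cells (%d low-depth, %d contaminated removed)",
        len(kept), counts.n_cells, len(lowdepth), len(contaminated),
    )
    return counts.subset_cells(kept), {"lowdepth": lowdepth, "contaminated": contaminated}
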