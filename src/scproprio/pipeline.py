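"""End-to-end orchestration: QC -> clustering -> consensus -> markers -> embedding.

Every run directory is stamped with the config hash and master seed;
reruns with the same inputs, config and seed reproduce byte-identical
tables.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .cluster import iter_cluster
from .config import PipelineConfig
from .consensus import bootstrap_coclustering, consensus_merge
from .containers import ClusterAssignment, CoClusterMatrix, CountMatrix, NormalizedMatrix
from .de import DEResult, MarkerTable, all_pairs_de, select_markers
from .modules import log_cpm
from .qc import cpm_normalize, filter_cells, qc_metrics

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    counts: CountMatrix  # QC-filtered
    norm: NormalizedMatrix
    qc_report: pd.DataFrame
    removed: dict[str, list[str]]
    reference: ClusterAssignment
    assignment: ClusterAssignment
    coclustering: CoClusterMatrix | None
    de: dict[tuple[str, str], DEResult]
    markers: MarkerTable | None
    embedding: pd.DataFrame | None
    pcs: pd.DataFrame | None
    stage_log: list[dict[str, Any]] = field(default_factory=list)


def embed_cells(
    norm: NormalizedMatrix,
    de: dict[tuple[str, str], DEResult],
    n_pcs: int = 20,
    seed: int = 0,
    fdr: float = 0.05,
    perplexity: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-D embedding of cells from their differential genes.

    Input construction follows the pipeline contract exactly: subset to
    all genes DE in any cluster pair (BH-adjusted p < ``fdr``), take
    log10(CPM+1), reduce to the top min(n_pcs, rank) principal
    components, then hand those to a stochastic-neighbor embedding with
    a fixed seed. Returns (2-D coordinates, PC scores), cells as rows.
    """
    de_genes = sorted(
        {g for res in de.values() for g in res.table.index[res.table["adj_p"] < fdr]}
    )
    if not de_genes:
        raise ValueError("no differentially expressed genes at the requested FDR")
    gidx = norm.gene_index()
    X = log_cpm(norm.values[[gidx[g] for g in de_genes]])  # genes x cells
    M = X.T - X.mean(axis=1)  # cells x genes, gene-centered
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    k = min(n_pcs, rank)
    if k < 1:
        raise ValueError("expression matrix has rank 0 on the DE genes")
    if k < n_pcs:
        log.info("PC count capped at matrix rank: %d", k)
    scores = u[:, :k] * s[:k]
    pcs = pd.DataFrame(
        scores, index=pd.Index(norm.cell_ids, name="cell_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    perp = min(perplexity, max(2.0, (len(norm.cell_ids) - 1) / 3.5))
    tsne = TSNE(n_components=2, perplexity=perp, random_state=seed, init="pca")
    coords = tsne.fit_transform(scores)
    emb = pd.DataFrame(coords, index=pcs.index, columns=["tsne1", "tsne2"])
    return emb, pcs


def run_pipeline(
    counts: CountMatrix,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run QC, iterative clustering, bootstrap consensus, DE/markers, embedding."""
    stage_log: list[dict[str, Any]] = []

    def stage(name: str, **info: Any) -> None:
        stage_log.append({"stage": name, **info})
        log.info("stage %s: %s", name, info)

    report = qc_metrics(
        counts,
        contaminant_genes=config.qc.contaminant_genes,
        min_genes=config.qc.min_genes,
        dialect=config.qc.contamination_dialect,
    )
    kept, removed = filter_cells(counts, report)
    stage(
        "qc",
        cells_in=counts.n_cells,
        cells_kept=kept.n_cells,
        removed_lowdepth=len(removed["lowdepth"]),
        removed_contaminated=len(removed["contaminated"]),
        dialect=config.qc.contamination_dialect,
    )
    norm = cpm_normalize(kept)

    reference = iter_cluster(kept, config.clustering, seed=config.seed)
    stage("iter_cluster", n_clusters=reference.n_clusters(),
          sizes=reference.cluster_sizes().to_dict())

    coclust: CoClusterMatrix | None = None
    assignment = reference
    if config.consensus.n_iter > 0:
        coclust, _archive = bootstrap_coclustering(
            kept,
            config.clustering,
            n_iter=config.consensus.n_iter,
            frac=config.consensus.frac,
            seed=config.seed,
        )
        assignment = consensus_merge(reference, coclust, config.consensus.coclust_threshold)
        stage("consensus", n_iter=config.consensus.n_iter,
              n_clusters=assignment.n_clusters())
    else:
        warnings.warn("consensus stage skipped (n_iter = 0)")
        stage("consensus", skipped=True)

    marker_labels = assignment.labels
    if config.markers.exclude_minor:
        majors = assignment.major_clusters()
        marker_labels = assignment.labels[assignment.labels.isin(majors)]

    de: dict[tuple[str, str], DEResult] = {}
    markers: MarkerTable | None = None
    if marker_labels.nunique() >= 2:
        marker_counts = kept.subset_cells(list(marker_labels.index))
        marker_norm = norm.subset_cells(list(marker_labels.index))
        de = all_pairs_de(marker_counts, marker_labels, d0=config.clustering.de.d0)
        markers = select_markers(
            de,
            marker_norm,
            marker_labels,
            tau_on=config.markers.tau_on,
            tau_off=config.markers.tau_off,
            fdr=config.clustering.de.fdr,
            lfc=config.clustering.de.lfc,
            min_pairs=config.markers.min_pairs,
        )
        stage("markers", n_pairs=len(de), n_markers=len(markers.table))
    else:
        warnings.warn("fewer than 2 (major) clusters; marker stage skipped")
        stage("markers", skipped=True)

    embedding = pcs = None
    if de:
        try:
            embedding, pcs = embed_cells(
                norm.subset_cells(list(marker_labels.index)),
                de,
                n_pcs=config.embedding.n_pcs,
                seed=config.seed,
                fdr=config.clustering.de.fdr,
                perplexity=config.embedding.perplexity,
            )
            stage("embedding", n_pcs=pcs.shape[1])
        except ValueError as err:
            warnings.warn(f"embedding skipped: {err}")
            stage("embedding", skipped=True, reason=str(err))

    result = PipelineResult(
        counts=kept, norm=norm, qc_report=report.table, removed=removed,
        reference=reference, assignment=assignment, coclustering=coclust,
        de=de, markers=markers, embedding=embedding, pcs=pcs, stage_log=stage_log,
    )
    if outdir is not None:
        write_outputs(result, config, Path(outdir))
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    config.save(outdir / "config.json")
    result.qc_report.to_csv(outdir / "qc_report.tsv", sep="\t")
    for key, ids in result.removed.items():
        (outdir / f"removed_{key}.txt").write_text("\n".join(ids) + ("\n" if ids else ""))

    labels = result.assignment.labels.to_frame()
    labels["minor"] = [result.assignment.minor_flags[c] for c in labels["cluster"]]
    labels.to_csv(outdir / "clusters.tsv", sep="\t")
    (outdir / "provenance.json").write_text(
        json.dumps({**stamp, "tree": result.assignment.tree}, indent=2, default=str)
    )
    if result.coclustering is not None:
        result.coclustering.to_frame().to_csv(outdir / "coclustering.tsv", sep="\t")
    if result.markers is not None:
        result.markers.table.to_csv(outdir / "markers.tsv", sep="\t")
    if result.embedding is not None:
        result.embedding.to_csv(outdir / "embedding.tsv", sep="\t")
    if result.pcs is not None:
        result.pcs.to_csv(outdir / "pcs.tsv", sep="\t")
    (outdir / "run_log.json").write_text(
        json.dumps({**stamp, "stages": result.stage_log}, indent=2, default=str)
    )
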