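"""Recursive cluster discovery with merge-by-DE-score robustness testing.

Each round, on the cells in scope: select high-Fano genes, detect
significant co-expression modules, place cells in eigengene space, split
them by Ward-linkage hierarchical clustering on cell-cell correlation
distance, then merge any pair of candidate clusters whose differential
expression is too weak (sum over DE genes of capped -log10 p below the
merge threshold). Recursion continues into each surviving cluster until
a scope yields no significant gene modules or no split survives merging.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Callable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import ClusteringConfig, DEConfig
from .containers import ClusterAssignment, CountMatrix, NormalizedMatrix
from .de import moderated_de
from .modules import fano_select, significant_modules
from .qc import cpm_normalize

log = logging.getLogger(__name__)


def split_once(
    eigengenes: np.ndarray, min_cluster_size: int = 4, k_max: int = 4
) -> np.ndarray:
    """One round of Ward-linkage splitting in eigengene space.

    Distance between two cells is 1 - Pearson r of their eigengene
    vectors (with a single eigengene, the absolute difference of the
    standardized value is used instead). The tree is cut at
    k = min(k_max, n // min_cluster_size); clusters smaller than
    ``min_cluster_size`` are reabsorbed into the cluster with highest
    mean inter-cell correlation. Returns integer labels (0-based).
    """
    n_modules, n_cells = eigengenes.shape
    if n_cells < 2 * min_cluster_size or n_modules < 1:
        return np.zeros(n_cells, dtype=int)

    if n_modules >= 2:
        r = np.corrcoef(eigengenes.T)
        dist = 1.0 - r
    else:
        e = eigengenes[0]
        s = e.std()
        e = e / s if s > 0 else e
        dist = np.abs(e[:, None] - e[None, :])
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    sim = 1.0 - dist  # used for small-cluster reabsorption

    k = min(k_max, n_cells // min_cluster_size)
    if k < 2:
        return np.zeros(n_cells, dtype=int)
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1

    # reabsorb clusters below the size floor, smallest first
    while True:
        ids, sizes = np.unique(labels, return_counts=True)
        small = ids[sizes < min_cluster_size]
        if len(small) == 0 or len(ids) == 1:
            break
        c = small[np.argmin(sizes[np.isin(ids, small)])]
        mask = labels == c
        best, best_sim = None, -np.inf
        for other in ids:
            if other == c:
                continue
            s = sim[np.ix_(mask, labels == other)].mean()
            if s > best_sim:
                best, best_sim = other, s
        labels[mask] = best

    # renumber to consecutive 0..k-1 in order of first appearance
    _, labels = np.unique(labels, return_index=False, return_inverse=True)
    return labels


def refine_labels(
    norm: NormalizedMatrix,
    labels: pd.Series,
    genes: list[str],
    min_cluster_size: int = 4,
    max_sweeps: int = 20,
) -> pd.Series:
    """Boundary refinement of final cluster labels.

    Hierarchical splitting commits each cell to one branch per level, so
    a handful of boundary cells can end up across the fence from their
    best-matching cluster. This pass reassigns each cell to the cluster
    whose members it correlates with best — cell-cell Pearson r on the
    log10(CPM+1) profile over the discovered module genes — repeating
    until stable. Clusters are never created, and clusters pushed below
    ``min_cluster_size`` are dissolved into their nearest neighbor;
    deterministic given its inputs.
    """
    if labels.nunique() < 2 or not genes:
        return labels
    from .modules import log_cpm  # local import to avoid cycle at module load

    gidx = norm.gene_index()
    sub = norm.subset_cells(list(labels.index))
    X = log_cpm(sub.values[[gidx[g] for g in genes]])
    sd = X.std(axis=1)
    X = X[sd > 0]
    if X.shape[0] < 2:
        return labels
    sim = np.corrcoef(X.T)

    lab = pd.factorize(labels.reindex(sub.cell_ids))[0]
    names = pd.factorize(labels.reindex(sub.cell_ids))[1]
    for _ in range(max_sweeps):
        ids = np.unique(lab)
        if len(ids) < 2:
            break
        onehot = (lab[:, None] == ids[None, :]).astype(float)
        sums = sim @ onehot
        sizes = onehot.sum(axis=0)
        own = onehot.astype(bool)
        sums[own] -= 1.0  # exclude self-similarity from the own-cluster mean
        denom = np.where(own, sizes[None, :] - 1.0, sizes[None, :])
        means = np.where(denom > 0, sums / np.where(denom > 0, denom, 1.0), -np.inf)
        new_lab = ids[np.argmax(means, axis=1)]
        ids2, counts2 = np.unique(new_lab, return_counts=True)
        for c in ids2[counts2 < min_cluster_size]:
            mask = new_lab == c
            rest = [o for o in ids2 if o != c and (new_lab == o).sum() >= min_cluster_size]
            if not rest:
                continue
            best = max(rest, key=lambda o: sim[np.ix_(mask, new_lab == o)].mean())
            new_lab[mask] = best
        if np.array_equal(new_lab, lab):
            break
        lab = new_lab

    return pd.Series(
        [str(names[c]) for c in lab], index=labels.index, name=labels.name
    )


def pair_merge_score(
    counts: CountMatrix,
    labels: pd.Series,
    pair: tuple[str, str],
    de_config: DEConfig = DEConfig(),
) -> float:
    """Cluster-pair distinctness: sum of capped -log10 raw p over DE genes.

    DE genes are those with BH-adjusted p < fdr and |log2FC| >= lfc; each
    contributes min(-log10 raw p, score_cap). Clusters with fewer than 2
    cells score 0 (insufficient replication, warned).
    """
    sizes = labels.value_counts()
    if sizes.get(pair[0], 0) < 2 or sizes.get(pair[1], 0) < 2:
        warnings.warn(f"cluster pair {pair} has a cluster with < 2 cells; score 0")
        return 0.0
    res = moderated_de(counts, labels, pair, d0=de_config.d0)
    de = res.de_genes(fdr=de_config.fdr, lfc=de_config.lfc)
    if de.empty:
        return 0.0
    return float(np.minimum(-np.log10(de["raw_p"]), de_config.score_cap).sum())


def merge_by_score(
    labels: pd.Series,
    scores: dict[tuple[str, str], float],
    threshold: float = 100.0,
    rescore: Callable[[pd.Series, tuple[str, str]], float] | None = None,
) -> tuple[pd.Series, list[dict]]:
    """Merge indistinct cluster pairs, smallest score first.

    Repeatedly merges the pair with the smallest score while that score
    is below ``threshold``; scores involving the merged cluster are then
    recomputed via ``rescore`` (required whenever a merge leaves more
    than one cluster). The merged cluster keeps the smaller id.
    """
    labels = labels.copy()
    scores = {tuple(sorted(p)): s for p, s in scores.items()}
    merges: list[dict] = []
    while True:
        clusters = sorted(labels.unique())
        if len(clusters) < 2:
            break
        pairs = [(a, b) for i, a in enumerate(clusters) for b in clusters[i + 1 :]]
        missing = [p for p in pairs if p not in scores]
        if missing:
            if rescore is None:
                raise ValueError(f"no score for pair(s) {missing} and no rescore callback")
            for p in missing:
                scores[p] = rescore(labels, p)
        best = min(pairs, key=lambda p: (scores[p], p))
        if scores[best] >= threshold:
            break
        a, b = best
        labels[labels == b] = a
        merges.append({"pair": [a, b], "score": scores[best]})
        scores = {p: s for p, s in scores.items() if b not in p and a not in p}
    return labels, merges


def iter_cluster(
    counts: CountMatrix, config: ClusteringConfig = ClusteringConfig(), seed: int = 0
) -> ClusterAssignment:
    """Full recursive cluster discovery on a QC-filtered count matrix."""
    norm = cpm_normalize(counts)
    scope_counter = itertools.count()
    leaves: list[list[str]] = []
    module_genes: set[str] = set()  # union over scopes, for the final boundary refinement

    def recurse(cell_ids: list[str], depth: int) -> dict:
        scope_seed = (seed + 1009 * next(scope_counter)) % (2**31)
        node: dict = {"n_cells": len(cell_ids), "depth": depth}
        if len(cell_ids) < 2 * config.min_cluster_size:
            node["leaf_reason"] = "too few cells"
            leaves.append(cell_ids)
            return node

        sub_norm = norm.subset_cells(cell_ids)
        try:
            genes = fano_select(sub_norm, k=config.n_top_genes)
        except ValueError:
            node["leaf_reason"] = "no expressed genes"
            leaves.append(cell_ids)
            return node
        mods = significant_modules(
            sub_norm, genes, config.module,
            n_perm=config.n_perm, alpha=config.alpha, seed=scope_seed,
        )
        node["n_modules"] = len(mods)
        for m in mods.modules:
            module_genes.update(m)
        if len(mods) == 0:
            node["leaf_reason"] = "no significant gene modules"
            leaves.append(cell_ids)
            return node

        cand = split_once(mods.eigengenes, config.min_cluster_size, config.k_max)
        node["candidate_k"] = int(cand.max()) + 1
        if cand.max() == 0:
            node["leaf_reason"] = "no split"
            leaves.append(cell_ids)
            return node

        cand_labels = pd.Series(
            [f"s{c}" for c in cand], index=pd.Index(cell_ids, name="cell_id")
        )
        sub_counts = counts.subset_cells(cell_ids)

        def rescore(lab: pd.Series, pair: tuple[str, str]) -> float:
            return pair_merge_score(sub_counts, lab, pair, config.de)

        merged, merges = merge_by_score(
            cand_labels, {}, threshold=config.merge_threshold, rescore=rescore
        )
        node["merges"] = merges
        groups = sorted(merged.unique())
        if len(groups) == 1:
            node["leaf_reason"] = "all candidates merged"
            leaves.append(cell_ids)
            return node
        node["children"] = [
            recurse(list(merged.index[merged == g]), depth + 1) for g in groups
        ]
        return node

    tree = recurse(list(counts.cell_ids), 0)

    labels = pd.Series(index=pd.Index(counts.cell_ids, name="cell_id"), dtype=object)
    for i, cells in enumerate(leaves):
        labels.loc[cells] = f"c{i + 1}"
    labels.name = "cluster"
    labels = refine_labels(
        norm, labels, sorted(module_genes), min_cluster_size=config.min_cluster_size
    )
    assignment = ClusterAssignment(
        labels=labels, tree=tree, minor_size_threshold=config.minor_size_threshold
    )
    log.info(
        "iter_cluster: %d cluster(s), sizes %s",
        assignment.n_clusters(),
        assignment.cluster_sizes().to_dict(),
    )
    return assignment
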