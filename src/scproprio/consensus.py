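"""Bootstrapped co-clustering consensus.

The full iterative clustering is repeated on random subsets of the cells
(default 100 runs at 80% without replacement); the co-clustering matrix
records, for each cell pair, the fraction of runs sampling both cells in
which they landed in the same cluster. Reference clusters (one full-data
clustering run under the master seed) whose mean cross co-clustering
exceeds the threshold (default 0.25, strict) are merged.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .cluster import iter_cluster
from .config import ClusteringConfig
from .containers import ClusterAssignment, CoClusterMatrix, CountMatrix

log = logging.getLogger(__name__)


def bootstrap_coclustering(
    counts: CountMatrix,
    config: ClusteringConfig = ClusteringConfig(),
    n_iter: int = 100,
    frac: float = 0.8,
    seed: int = 0,
) -> tuple[CoClusterMatrix, list[pd.Series]]:
    """Repeat iter_cluster on random cell subsets and tally co-clustering.

    Run r uses the derived seed ``seed + r`` for both the subsample and
    the clustering. Returns the co-clustering matrix and the per-run
    label archive. Pairs never co-sampled are NaN.
    """
    if not 0 < frac <= 1:
        raise ValueError("subsample fraction must lie in (0, 1]")
    n = counts.n_cells
    n_sample = int(np.floor(frac * n))
    if n_sample < 2 * config.min_cluster_size:
        raise ValueError(
            f"subsample of {n_sample} cells is below 2 x min_cluster_size "
            f"({2 * config.min_cluster_size})"
        )

    idx_of = {c: i for i, c in enumerate(counts.cell_ids)}
    same = np.zeros((n, n), dtype=np.int64)
    both = np.zeros((n, n), dtype=np.int64)
    archive: list[pd.Series] = []
    for r in range(n_iter):
        run_seed = (seed + r) % (2**31)
        rng = np.random.default_rng(run_seed)
        sampled = np.sort(rng.choice(n, size=n_sample, replace=False))
        sub = counts.subset_cells([counts.cell_ids[i] for i in sampled])
        assignment = iter_cluster(sub, config, seed=run_seed)
        archive.append(assignment.labels)
        codes = pd.factorize(assignment.labels.reindex(sub.cell_ids))[0]
        eq = (codes[:, None] == codes[None, :]).astype(np.int64)
        ix = np.ix_(sampled, sampled)
        both[ix] += 1
        same[ix] += eq

    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(both > 0, same / np.where(both > 0, both, 1), np.nan)
    coclust = CoClusterMatrix(
        proportions=prop,
        cosample_counts=both,
        cell_ids=list(counts.cell_ids),
        n_iter=n_iter,
        subsample_frac=frac,
    )
    return coclust, archive


def coclustering_from_archive(
    cell_ids: list[str], archive: list[pd.Series]
) -> CoClusterMatrix:
    """Recompute the co-clustering matrix from archived run labels.

    Brute-force tally used for cross-checking ``bootstrap_coclustering``.
    """
    n = len(cell_ids)
    pos = {c: i for i, c in enumerate(cell_ids)}
    same = np.zeros((n, n), dtype=np.int64)
    both = np.zeros((n, n), dtype=np.int64)
    for labels in archive:
        cells = list(labels.index)
        for a in cells:
            for b in cells:
                both[pos[a], pos[b]] += 1
                if labels[a] == labels[b]:
                    same[pos[a], pos[b]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(both > 0, same / np.where(both > 0, both, 1), np.nan)
    return CoClusterMatrix(prop, both, list(cell_ids), len(archive), float("nan"))


def mean_cross_coclustering(
    coclust: CoClusterMatrix, labels: pd.Series, a: str, b: str
) -> float:
    """Mean defined co-clustering over all cross-cluster cell pairs (NaN-free)."""
    lab = labels.reindex(coclust.cell_ids)
    ma = (lab == a).to_numpy()
    mb = (lab == b).to_numpy()
    block = coclust.proportions[np.ix_(ma, mb)]
    defined = ~np.isnan(block)
    if not defined.any():
        warnings.warn(f"cluster pair ({a}, {b}) has no co-sampled cell pairs; mean treated as 0")
        return 0.0
    return float(block[defined].mean())


def consensus_merge(
    reference: ClusterAssignment,
    coclust: CoClusterMatrix,
    threshold: float = 0.25,
) -> ClusterAssignment:
    """Merge reference clusters with mean cross co-clustering > threshold.

    Iteratively merges the highest-mean pair (strictly above threshold),
    recomputing means after each merge.
    """
    labels = reference.labels.copy()
    merges: list[dict] = []
    while True:
        clusters = sorted(labels.unique())
        if len(clusters) < 2:
            break
        best, best_mean = None, -np.inf
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                m = mean_cross_coclustering(coclust, labels, a, b)
                if m > best_mean:
                    best, best_mean = (a, b), m
        if best is None or best_mean <= threshold:
            break
        a, b = best
        labels[labels == b] = a
        merges.append({"pair": [a, b], "mean_coclustering": best_mean})
        log.info("consensus merge %s + %s (mean co-clustering %.3f)", a, b, best_mean)

    tree = {"reference_tree": reference.tree, "consensus_merges": merges}
    return ClusterAssignment(
        labels=labels, tree=tree, minor_size_threshold=reference.minor_size_threshold
    )
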