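"""Pairwise differential expression and subtype-marker selection.

One documented test serves both the cluster-merge score and marker
discovery: a moderated two-sample t on log2(CPM+1), with gene-wise
variances shrunk toward the median gene variance,

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

where d is the pooled residual degrees of freedom, d0 = 4 prior degrees
of freedom, and s0^2 the median pooled gene variance; the t statistic is
referred to a t distribution with d0 + d degrees of freedom. As d0 -> 0
this reduces to an ordinary pooled t test; as d0 -> infinity every gene
is tested against the common variance s0^2.

Markers are genes significant across multiple cluster pairs with, in
addition, near-binary (on/off) expression: detected in at least tau_on
of the cells of some cluster and at most tau_off of the cells of some
other cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

D0_DEFAULT = 4.0


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Moderated-t differential expression between one cluster pair."""

    pair: tuple[str, str]
    table: pd.DataFrame  # index gene id: log2_fold_change, raw_p, adj_p, direction
    n_cells: tuple[int, int] = (0, 0)

    def de_genes(self, fdr: float = 0.05, lfc: float = 1.0) -> pd.DataFrame:
        t = self.table
        return t[(t["adj_p"] < fdr) & (t["log2_fold_change"].abs() >= lfc)]


def _log2_cpm(counts_values: np.ndarray) -> np.ndarray:
    totals = counts_values.sum(axis=0).astype(float)
    safe = np.where(totals == 0, 1.0, totals)
    return np.log2(counts_values / safe * 1e6 + 1.0)


def moderated_de(counts, labels: pd.Series, pair: tuple[str, str], d0: float = D0_DEFAULT) -> DEResult:
    """Moderated t-test on log2(CPM+1) between the two labelled groups.

    ``labels`` maps cell id -> cluster id and must cover the matrix's
    cells; both groups need at least 2 cells.
    """
    lab = labels.reindex(counts.cell_ids)
    mask1 = (lab == pair[0]).to_numpy()
    mask2 = (lab == pair[1]).to_numpy()
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each cluster needs >= 2 cells (got {n1}, {n2})")

    X = _log2_cpm(counts.values)
    x1, x2 = X[:, mask1], X[:, mask2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    s0_sq = float(np.median(s2))
    s2_mod = (d0 * s0_sq + d * s2) / (d0 + d)

    diff = m1 - m2
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf))
    raw_p = 2.0 * stats.t.sf(np.abs(t), df=d0 + d)
    raw_p = np.clip(raw_p, np.nextafter(0, 1), 1.0)
    adj_p = bh_adjust(raw_p)

    table = pd.DataFrame(
        {
            "log2_fold_change": diff,
            "t": t,
            "raw_p": raw_p,
            "adj_p": adj_p,
            "direction": np.where(diff >= 0, "up_in_first", "up_in_second"),
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    return DEResult(pair, table, (n1, n2))


def all_pairs_de(counts, labels: pd.Series, clusters: list[str] | None = None, d0: float = D0_DEFAULT) -> dict[tuple[str, str], DEResult]:
    """Moderated DE for every unordered cluster pair."""
    if clusters is None:
        clusters = sorted(labels.unique())
    out: dict[tuple[str, str], DEResult] = {}
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            out[(a, b)] = moderated_de(counts, labels, (a, b), d0=d0)
    return out


@dataclass
class MarkerTable:
    """Selected subtype markers with their on/off cluster structure."""

    table: pd.DataFrame  # index gene id, ranked
    tau_on: float = 0.7
    tau_off: float = 0.2

    def markers(self) -> list[str]:
        return list(self.table.index)

    def clusters_on(self, gene: str) -> list[str]:
        return list(self.table.loc[gene, "clusters_on"])


def select_markers(
    de: dict[tuple[str, str], DEResult],
    norm,
    labels: pd.Series,
    tau_on: float = 0.7,
    tau_off: float = 0.2,
    fdr: float = 0.05,
    lfc: float = 1.0,
    min_pairs: int = 2,
) -> MarkerTable:
    """Markers: multi-pair significant genes with binary on/off expression.

    A gene qualifies if it is significant (BH-adjusted p < ``fdr`` and
    |log2 fold change| >= ``lfc``) in at least ``min_pairs`` cluster
    pairs, is detected (CPM > 0) in >= ``tau_on`` of the cells of at
    least one cluster and <= ``tau_off`` of the cells of at least one
    other. Ranked by number of significant pairs, then max |log2FC|.
    """
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("marker selection needs at least 2 clusters")

    lab = labels.reindex(norm.cell_ids)
    detected = norm.values > 0
    frac_on = pd.DataFrame(
        {c: detected[:, (lab == c).to_numpy()].mean(axis=1) for c in clusters},
        index=norm.gene_ids,
    )

    n_sig = pd.Series(0, index=pd.Index(norm.gene_ids, name="gene_id"))
    max_lfc = pd.Series(0.0, index=n_sig.index)
    for res in de.values():
        sig = res.de_genes(fdr=fdr, lfc=lfc)
        n_sig.loc[sig.index] += 1
        max_lfc.loc[sig.index] = np.maximum(
            max_lfc.loc[sig.index], sig["log2_fold_change"].abs()
        )

    clusters_on = frac_on.apply(lambda row: [c for c in clusters if row[c] >= tau_on], axis=1)
    clusters_off = frac_on.apply(lambda row: [c for c in clusters if row[c] <= tau_off], axis=1)
    keep = (
        (n_sig >= min_pairs)
        & (clusters_on.str.len() >= 1)
        & (clusters_off.str.len() >= 1)
    )
    table = pd.DataFrame(
        {
            "n_pairs_significant": n_sig,
            "max_abs_log2fc": max_lfc,
            "clusters_on": clusters_on,
            "clusters_off": clusters_off,
            "max_cpm": norm.values.max(axis=1),
        }
    )[keep]
    table = table.sort_values(
        ["n_pairs_significant", "max_abs_log2fc"], ascending=[False, False], kind="stable"
    )
    return MarkerTable(table, tau_on, tau_off)
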