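"""Gene-set enrichment: classic and elim Fisher tests.

The classic test is a one-sided hypergeometric (Fisher) test of overlap
between a study gene list and each set, BH-adjusted across sets. The
elim variant walks the set hierarchy children-before-parents; when a
set tests significant at ``sig_cutoff``, its study genes are removed
from the annotations of all its ancestors before those are tested, so
parents are not called significant merely because of a significant
child. Sets annotating fewer than ``node_size`` genes are skipped. A
reported set passes the final filters iff its overlap is at least 5 and
both adjusted p-values (classic and elim) are below 0.01.

No ontology is bundled: users supply sets (GMT) plus an optional
child -> parent table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

MIN_OVERLAP = 5
ADJ_P_CUTOFF = 0.01


@dataclass
class GeneSetCollection:
    """Named gene sets, an optional parent DAG, and the gene universe."""

    sets: dict[str, list[str]]
    universe: list[str]
    parents: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, genes in self.sets.items():
            extra = set(genes) - uni
            if extra:
                raise ValueError(f"set {name!r} contains genes outside the universe: {sorted(extra)[:5]}")
        g = self.parent_graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent graph is cyclic")

    def parent_graph(self) -> nx.DiGraph:
        """Directed graph with edges child -> parent."""
        g = nx.DiGraph()
        g.add_nodes_from(self.sets)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        return g

    def ancestors(self, name: str) -> set[str]:
        return nx.descendants(self.parent_graph(), name)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # index set id: overlap, p_classic, p_elim, adj_p_*, passes_filters

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["passes_filters"]]


def _hypergeom_p(overlap: int, universe_n: int, set_n: int, study_n: int) -> float:
    """P(X >= overlap) for overlap of a study list with a set, under random draws."""
    return float(stats.hypergeom.sf(overlap - 1, universe_n, set_n, study_n))


def enrich_classic(study: list[str], sets: GeneSetCollection) -> EnrichmentResult:
    """One-sided hypergeometric enrichment over all sets (no hierarchy)."""
    if not sets.universe:
        raise ValueError("empty gene universe")
    study_set = set(study)
    extra = study_set - set(sets.universe)
    if extra:
        raise ValueError(f"study genes outside universe: {sorted(extra)[:5]}")
    rows = {}
    m = len(sets.universe)
    for name, genes in sets.sets.items():
        ov = len(study_set & set(genes))
        rows[name] = {"overlap": ov, "p_classic": _hypergeom_p(ov, m, len(genes), len(study_set))}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "set_id"
    table["p_elim"] = table["p_classic"]
    _finalize(table)
    return EnrichmentResult(table)


def enrich_elim(
    study: list[str],
    sets: GeneSetCollection,
    sig_cutoff: float = 0.01,
    node_size: int = MIN_OVERLAP,
) -> EnrichmentResult:
    """Hierarchy-aware enrichment: eliminate significant children's genes
    from ancestors before testing them.

    Sets are processed in reverse topological order of the child->parent
    graph (children first). For a flat collection this reduces exactly to
    the classic test.
    """
    study_set = set(study)
    extra = study_set - set(sets.universe)
    if extra:
        raise ValueError(f"study genes outside universe: {sorted(extra)[:5]}")
    g = sets.parent_graph()
    order = list(nx.topological_sort(g))  # children before parents (edges child->parent)

    m = len(sets.universe)
    current: dict[str, set[str]] = {name: set(genes) for name, genes in sets.sets.items()}
    tested = [name for name in order if len(sets.sets.get(name, [])) >= node_size]
    skipped = [name for name in order if name not in set(tested)]

    rows: dict[str, dict] = {}
    ancestors_cache = {name: nx.descendants(g, name) for name in sets.sets}
    for name in order:
        if name not in sets.sets or name in skipped:
            continue
        genes_now = current[name]
        ov_now = len(study_set & genes_now)
        p_elim = _hypergeom_p(ov_now, m, len(genes_now), len(study_set))
        genes_orig = set(sets.sets[name])
        ov_orig = len(study_set & genes_orig)
        p_classic = _hypergeom_p(ov_orig, m, len(genes_orig), len(study_set))
        rows[name] = {"overlap": ov_orig, "overlap_elim": ov_now, "p_classic": p_classic, "p_elim": p_elim}
        if p_elim < sig_cutoff:
            to_remove = study_set & set(sets.sets[name])
            for anc in ancestors_cache[name]:
                if anc in current:
                    current[anc] -= to_remove

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "set_id"
    if table.empty:
        table = pd.DataFrame(
            columns=["overlap", "overlap_elim", "p_classic", "p_elim"], dtype=float
        )
        table.index.name = "set_id"
    _finalize(table)
    return EnrichmentResult(table)


def _finalize(table: pd.DataFrame) -> None:
    if table.empty:
        for col in ("adj_p_classic", "adj_p_elim"):
            table[col] = pd.Series(dtype=float)
        table["passes_filters"] = pd.Series(dtype=bool)
        return
    table["adj_p_classic"] = bh_adjust(table["p_classic"].to_numpy())
    table["adj_p_elim"] = bh_adjust(table["p_elim"].to_numpy())
    table["passes_filters"] = (
        (table["overlap"] >= MIN_OVERLAP)
        & (table["adj_p_classic"] < ADJ_P_CUTOFF)
        & (table["adj_p_elim"] < ADJ_P_CUTOFF)
    )
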