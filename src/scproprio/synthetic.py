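"""Synthetic UMI count data with planted ground truth.

Generates plate-seq-like count matrices that carry the statistical
structure the clustering pipeline assumes: negative-binomial counts,
log-normal per-cell sequencing depth, a handful of planted cell clusters
distinguished by on/off marker programs, glial-contaminated cells
(admixture of a neuronal baseline with boosted Apoe/Mpz/Mbp), and
low-depth cells rescaled to a target number of detected genes. Every
planted fact is recorded so downstream stages can be scored exactly.

The generative model is a stand-in chosen for testability (counts are
NB with variance mu + dispersion*mu^2; depth is log-normal; marker
programs act multiplicatively on rates); it is not a claim about the
data-generating process of any particular experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import CountMatrix

CONTAMINANT_LABEL = "contaminant"
_DEFAULT_CONTAMINANTS = ("Apoe", "Mpz", "Mbp")


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of one synthetic dataset.

    Defaults reproduce the benchmark study design: 166 cells in planted
    clusters proportioned 51/31/28/28/28, 20 marker genes per cluster,
    plus flagged low-depth and satellite-contaminated cells.

    Marker programs are on/off: in its home cluster a marker's rate is
    ``baseline_mean * marker_fold_change`` (the ON level); in every other
    cluster it leaks only ``marker_off_fraction`` of baseline (default
    1%, i.e. essentially undetected), matching the near-binary expression
    of real subtype markers. ``n_genes`` includes the three named glial
    contaminant genes, which are silent in all non-contaminated cells
    (neurons do not express them), so the QC thresholds separate the
    planted sets exactly.
    """

    n_genes: int = 2500
    cluster_sizes: tuple[int, ...] = (51, 31, 28, 28, 28)
    marker_genes_per_cluster: int = 20
    marker_fold_change: float = 4.0
    marker_off_fraction: float = 0.01
    baseline_mean: float = 1.0
    nb_dispersion: float = 0.25
    libsize_lognormal_mu: float = float(np.log(30_000.0))
    libsize_lognormal_sigma: float = 0.35
    n_contaminant_cells: int = 8
    contaminant_genes: tuple[str, ...] = _DEFAULT_CONTAMINANTS
    contaminant_boost: float = 150.0
    n_lowdepth_cells: int = 10
    lowdepth_gene_target: int = 1200
    seed: int = 0

    def validate(self) -> None:
        if len(self.cluster_sizes) == 0 or sum(self.cluster_sizes) < 1:
            raise ValueError("empty design: at least one nonempty cluster is required")
        if any(s < 0 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be nonnegative")
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        if not 0 <= self.marker_off_fraction <= 1:
            raise ValueError("marker_off_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.baseline_mean <= 0 or self.contaminant_boost <= 0:
            raise ValueError("rates must be positive")
        if not 0 < self.lowdepth_gene_target < 2000:
            raise ValueError("lowdepth_gene_target must lie in (0, 2000)")
        n_marker = len(self.cluster_sizes) * self.marker_genes_per_cluster
        if self.n_genes < n_marker + len(self.contaminant_genes):
            raise ValueError(
                "n_genes too small for the requested marker programs and contaminant genes"
            )


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    cell_labels: pd.Series  # cell id -> cluster id (contaminants labelled separately)
    marker_map: dict[str, list[str]]
    flagged_lowdepth: list[str] = field(default_factory=list)
    flagged_contaminant: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cell_labels": {str(c): str(l) for c, l in self.cell_labels.items()},
            "marker_map": {k: list(v) for k, v in self.marker_map.items()},
            "flagged_lowdepth": list(self.flagged_lowdepth),
            "flagged_contaminant": list(self.flagged_contaminant),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        labels = pd.Series(d["cell_labels"], name="cluster")
        labels.index.name = "cell_id"
        return cls(
            cell_labels=labels,
            marker_map={k: list(v) for k, v in d["marker_map"].items()},
            flagged_lowdepth=list(d["flagged_lowdepth"]),
            flagged_contaminant=list(d["flagged_contaminant"]),
        )


def _gene_ids(spec: SyntheticSpec) -> list[str]:
    n_plain = spec.n_genes - len(spec.contaminant_genes)
    ids = [f"g{i:05d}" for i in range(n_plain)]
    ids.extend(spec.contaminant_genes)
    return ids


def _rate_programs(spec: SyntheticSpec) -> tuple[list[str], dict[str, np.ndarray], dict[str, list[str]]]:
    """Per-cluster expression-rate vectors plus the marker map.

    Base rate is ``baseline_mean`` for ordinary genes and 0 for the
    contaminant genes. Marker genes are ON (baseline x fold change) in
    their home cluster and leak only ``marker_off_fraction`` of baseline
    everywhere else. Contaminated cells run the no-subtype baseline
    program (all markers off) with the glial genes boosted on top.
    """
    gene_ids = _gene_ids(spec)
    n_cont = len(spec.contaminant_genes)
    base = np.full(spec.n_genes, spec.baseline_mean, dtype=float)
    if n_cont:
        base[-n_cont:] = 0.0

    m = spec.marker_genes_per_cluster
    n_clusters = len(spec.cluster_sizes)
    all_marker_idx = np.arange(n_clusters * m)

    programs: dict[str, np.ndarray] = {}
    marker_map: dict[str, list[str]] = {}
    for k in range(n_clusters):
        cid = f"cluster{k + 1}"
        rates = base.copy()
        rates[all_marker_idx] = spec.baseline_mean * spec.marker_off_fraction
        rates[k * m : (k + 1) * m] = spec.baseline_mean * spec.marker_fold_change
        programs[cid] = rates
        marker_map[cid] = gene_ids[k * m : (k + 1) * m]

    cont = base.copy()
    cont[all_marker_idx] = spec.baseline_mean * spec.marker_off_fraction
    if n_cont:
        cont[-n_cont:] = spec.baseline_mean * spec.contaminant_boost
    programs[CONTAMINANT_LABEL] = cont
    return gene_ids, programs, marker_map


def _nb_zero_prob(mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return np.exp(-mu)
    return (1.0 + dispersion * mu) ** (-1.0 / dispersion)


def _lowdepth_scale(mean_vec: np.ndarray, dispersion: float, target: float) -> float:
    """Depth-scaling factor at which the expected detected-gene count hits target."""

    def expected_detected(s: float) -> float:
        return float(np.sum(1.0 - _nb_zero_prob(s * mean_vec, dispersion)))

    if expected_detected(1.0) <= target:
        return 1.0
    return brentq(lambda s: expected_detected(s) - target, 1e-8, 1.0, xtol=1e-10)


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    lam = np.zeros_like(mu)
    pos = mu > 0
    lam[pos] = rng.gamma(1.0 / dispersion, dispersion * mu[pos])
    return rng.poisson(lam)


def simulate_counts(spec: SyntheticSpec) -> tuple[CountMatrix, PlantedTruth]:
    """Generate one UMI count matrix with planted truth.

    Cell order: planted clusters in design order, then low-depth cells
    (assigned round-robin to cluster programs), then contaminated cells.
    Generation is bit-identical for identical specs (single seeded RNG,
    fixed draw order).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gene_ids, programs, marker_map = _rate_programs(spec)
    cluster_ids = [f"cluster{k + 1}" for k in range(len(spec.cluster_sizes))]

    cell_programs: list[str] = []
    for cid, size in zip(cluster_ids, spec.cluster_sizes):
        cell_programs.extend([cid] * size)
    n_core = len(cell_programs)
    for i in range(spec.n_lowdepth_cells):
        cell_programs.append(cluster_ids[i % len(cluster_ids)])
    cell_programs.extend([CONTAMINANT_LABEL] * spec.n_contaminant_cells)

    n_cells = len(cell_programs)
    cell_ids = [f"C{i:04d}" for i in range(n_cells)]
    lowdepth_ids = cell_ids[n_core : n_core + spec.n_lowdepth_cells]
    contaminant_ids = cell_ids[n_core + spec.n_lowdepth_cells :]

    libsizes = rng.lognormal(spec.libsize_lognormal_mu, spec.libsize_lognormal_sigma, n_cells)

    counts = np.zeros((spec.n_genes, n_cells), dtype=np.int64)
    lowdepth_set = set(lowdepth_ids)
    for j, (cell, prog) in enumerate(zip(cell_ids, cell_programs)):
        rates = programs[prog]
        mu = libsizes[j] * rates / rates.sum()
        if cell in lowdepth_set:
            mu = mu * _lowdepth_scale(mu, spec.nb_dispersion, spec.lowdepth_gene_target)
        counts[:, j] = _sample_counts(rng, mu, spec.nb_dispersion)

    meta = pd.DataFrame(
        {"stage": "adult", "batch": "b0"}, index=pd.Index(cell_ids, name="cell_id")
    )
    matrix = CountMatrix(counts, gene_ids, cell_ids, meta)
    labels = pd.Series(cell_programs, index=pd.Index(cell_ids, name="cell_id"), name="cluster")
    truth = PlantedTruth(
        cell_labels=labels,
        marker_map=marker_map,
        flagged_lowdepth=list(lowdepth_ids),
        flagged_contaminant=list(contaminant_ids),
    )
    return matrix, truth


def simulate_timecourse(
    specs: Sequence[SyntheticSpec],
    coexpression_decay: float,
    stage_names: Sequence[str] | None = None,
) -> list[tuple[CountMatrix, PlantedTruth]]:
    """Generate a developmental time course of count matrices.

    The last spec is the mature ("adult") stage and keeps its full marker
    fold change; each step back in time shrinks the fold change toward 1
    by ``coexpression_decay``, so within-cluster marker co-expression
    weakens monotonically toward earlier stages (decay 1 leaves all
    stages identically designed; decay 0 removes all structure before
    the final stage).
    """
    if len(specs) < 2:
        raise ValueError("a time course needs at least 2 stages")
    if not 0.0 <= coexpression_decay <= 1.0:
        raise ValueError("coexpression_decay must lie in [0, 1]")
    n_stages = len(specs)
    if stage_names is None:
        stage_names = [f"stage{i}" for i in range(n_stages)]

    out: list[tuple[CountMatrix, PlantedTruth]] = []
    for i, spec in enumerate(specs):
        steps_back = n_stages - 1 - i
        shrink = coexpression_decay**steps_back if steps_back > 0 else 1.0
        fold = 1.0 + (spec.marker_fold_change - 1.0) * shrink
        # the off-state leak relaxes toward baseline (1.0) at early stages
        off = spec.marker_off_fraction**shrink if spec.marker_off_fraction > 0 else (
            0.0 if shrink > 0 else 1.0
        )
        stage_spec = replace(spec, marker_fold_change=fold, marker_off_fraction=off)
        matrix, truth = simulate_counts(stage_spec)
        matrix.cell_meta["stage"] = stage_names[i]
        matrix.cell_ids = [f"{stage_names[i]}_{c}" for c in matrix.cell_ids]
        matrix.cell_meta.index = pd.Index(matrix.cell_ids, name="cell_id")
        truth.cell_labels.index = pd.Index(matrix.cell_ids, name="cell_id")
        truth.flagged_lowdepth = [f"{stage_names[i]}_{c}" for c in truth.flagged_lowdepth]
        truth.flagged_contaminant = [f"{stage_names[i]}_{c}" for c in truth.flagged_contaminant]
        out.append((matrix, truth))
    return out


def benchmark_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default 166-cell benchmark design (plus flagged QC cells)."""
    return replace(SyntheticSpec(seed=seed), **overrides)
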