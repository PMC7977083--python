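"""High-variance gene selection and co-expression module detection.

The inner engine of each clustering iteration: pick the most
overdispersed genes (Fano factor = variance/mean on CPM), build an
unsigned correlation network on log10(CPM+1), cluster genes by average
linkage on 1 - |r|^power, extract coherent branches as modules, test
each module's co-expression against a per-gene permutation null, and
summarize surviving modules by their eigengenes (first principal
component of the z-scored module submatrix).

Branch extraction: a dendrogram branch becomes a module iff (a) it has
at least ``min_module_size`` genes, (b) its internal merge height is at
most ``cutheight``, (c) it joins its sibling at least ``min_gap`` above
its own height (i.e. the branch is detached from the background), and
(d) none of its sub-branches qualify on their own (deepest coherent
structure wins). With well-separated data this reduces to a static cut
at ``cutheight``; on finite samples it additionally ignores the diffuse
background tree that null correlations (|r| ~ sqrt(2/pi n)) create below
any fixed cut height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.cluster.hierarchy import linkage

from .containers import GeneModuleSet, NormalizedMatrix


@dataclass(frozen=True)
class ModuleParams:
    power: float = 1.0
    cutheight: float = 0.995
    min_module_size: int = 10
    min_gap: float = 0.1
    corr_sig: float = 0.05  # per-pair significance for the branch coherence floor
    detect_frac: float = 2 / 3  # cell fraction used for detection vs held-out validation
    use_tom: bool = False  # optional topological-overlap transform


def critical_abs_corr(n_cells: int, sig: float = 0.01) -> float:
    """|r| above which a single Pearson correlation is two-sided significant.

    Used as the coherence floor for candidate branches: hierarchical
    trees over thousands of genes always contain branches slightly
    tighter than average by selection alone, so a branch only counts as
    a module if its mean within-branch correlation would be individually
    significant at ``sig`` given the cell count.
    """
    df = n_cells - 2
    if df < 1:
        return 1.0
    from scipy import stats

    t = stats.t.ppf(1.0 - sig / 2.0, df)
    return float(t / np.sqrt(df + t * t))


def log_cpm(values: np.ndarray, base: float = 10.0) -> np.ndarray:
    """log(CPM + 1); base 10 by default (the clustering convention)."""
    return np.log1p(values) / np.log(base)


def fano_select(norm: NormalizedMatrix, k: int = 6000) -> list[str]:
    """Top-k genes by Fano factor (sample variance / mean) on CPM.

    Zero-mean genes are excluded; ties broken by input gene order.
    """
    means = norm.values.mean(axis=1)
    if not (means > 0).any():
        raise ValueError("all-zero matrix: no gene has positive mean CPM")
    if norm.n_cells > 1:
        var = norm.values.var(axis=1, ddof=1)
    else:
        var = np.zeros(norm.n_genes)
    eligible = means > 0
    fano = np.where(eligible, var / np.where(eligible, means, 1.0), -np.inf)
    n_eligible = int(eligible.sum())
    if k > n_eligible:
        warnings.warn(
            f"requested top {k} genes but only {n_eligible} have positive mean; returning all"
        )
    order = np.argsort(-fano, kind="stable")[: min(k, n_eligible)]
    return [norm.gene_ids[i] for i in order]


def _tom(adj: np.ndarray) -> np.ndarray:
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _branch_modules(
    Z: np.ndarray,
    n: int,
    cutheight: float,
    min_gap: float,
    min_module_size: int,
    min_adjacency: float = 0.0,
) -> list[list[int]]:
    """Extract detached coherent branches from a linkage tree (see module docstring).

    Average-linkage merge heights are mean cross-branch distances, so the
    mean within-branch distance (hence mean adjacency) of every node is
    computed exactly bottom-up and compared with the coherence floor.
    """
    n_nodes = n + Z.shape[0]
    size = np.ones(n_nodes, dtype=int)
    height = np.zeros(n_nodes)
    dist_sum = np.zeros(n_nodes)  # sum of pairwise distances within the branch
    members: list[list[int] | None] = [[i] for i in range(n)] + [None] * Z.shape[0]
    submods: list[list[list[int]]] = [[] for _ in range(n_nodes)]
    eligible = np.zeros(n_nodes, dtype=bool)
    eligible[:n] = min_module_size <= 1  # single-gene leaves only if allowed

    def resolve(child: int, join_h: float) -> list[list[int]]:
        if size[child] < min_module_size:
            return []
        if submods[child]:
            return submods[child]
        if eligible[child] and (join_h - height[child]) >= min_gap:
            return [members[child]]  # type: ignore[list-item]
        return []

    for row in range(Z.shape[0]):
        node = n + row
        left, right = int(Z[row, 0]), int(Z[row, 1])
        h = float(Z[row, 2])
        size[node] = size[left] + size[right]
        height[node] = h
        dist_sum[node] = dist_sum[left] + dist_sum[right] + h * size[left] * size[right]
        members[node] = members[left] + members[right]  # type: ignore[operator]
        submods[node] = resolve(left, h) + resolve(right, h)
        n_pairs = size[node] * (size[node] - 1) / 2.0
        mean_adj = 1.0 - dist_sum[node] / n_pairs
        eligible[node] = (
            size[node] >= min_module_size and h <= cutheight and mean_adj >= min_adjacency
        )

    root = n_nodes - 1
    return resolve(root, np.inf)


def detect_modules(
    norm: NormalizedMatrix, genes: list[str], params: ModuleParams = ModuleParams()
) -> GeneModuleSet:
    """Detect co-expression gene modules (before the significance filter)."""
    gidx = norm.gene_index()
    rows = [gidx[g] for g in genes]
    if len(rows) < params.min_module_size:
        return GeneModuleSet([], np.zeros((0, norm.n_cells)), list(norm.cell_ids), [], asdict(params))

    X = log_cpm(norm.values[rows])
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.any() or keep.sum() < params.min_module_size:
        return GeneModuleSet([], np.zeros((0, norm.n_cells)), list(norm.cell_ids), [], asdict(params))
    genes_kept = [g for g, k in zip(genes, keep) if k]
    X = X[keep]

    # correlations via standardized matmul (the matrix is large; avoid copies)
    Zs = (X - X.mean(axis=1, keepdims=True)) / (X.std(axis=1, keepdims=True) * np.sqrt(X.shape[1]))
    r = Zs @ Zs.T
    adj = np.abs(r, out=r)
    if params.power != 1.0:
        np.power(adj, params.power, out=adj)
    if params.use_tom:
        adj = _tom(adj)

    if len(genes_kept) == 1:
        idx_modules = [[0]] if params.min_module_size <= 1 else []
    else:
        iu = np.triu_indices(adj.shape[0], 1)
        condensed = np.clip(1.0 - adj[iu], 0.0, None)
        Z = linkage(condensed, method="average")
        floor = critical_abs_corr(norm.n_cells, params.corr_sig) ** params.power
        idx_modules = _branch_modules(
            Z,
            len(genes_kept),
            params.cutheight,
            params.min_gap,
            params.min_module_size,
            min_adjacency=floor,
        )

    modules = [sorted(genes_kept[i] for i in idx) for idx in idx_modules]
    modules.sort(key=lambda m: (-len(m), m[0]))
    eig = eigengenes(norm, modules) if modules else np.zeros((0, norm.n_cells))
    return GeneModuleSet(modules, eig, list(norm.cell_ids), [], asdict(params))


def module_significance(
    moduleset: GeneModuleSet,
    norm: NormalizedMatrix,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> GeneModuleSet:
    """Permutation test for co-expression beyond chance.

    The statistic is the mean absolute pairwise correlation within the
    module (on log10(CPM+1)); the null permutes each gene's values
    across cells independently. A module is kept iff its observed
    statistic exceeds the (1 - alpha) quantile of its null;
    p = (1 + #{null >= obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(moduleset) == 0:
        return moduleset
    rng = np.random.default_rng(seed)
    gidx = norm.gene_index()

    kept_modules: list[list[str]] = []
    kept_rows: list[int] = []
    pvals: list[float] = []
    for mi, module in enumerate(moduleset.modules):
        X = log_cpm(norm.values[[gidx[g] for g in module]])
        sd = X.std(axis=1)
        X = X[sd > 0]
        m, n = X.shape
        if m < 2:
            continue  # degenerate module: no testable co-expression
        Zs = (X - X.mean(axis=1, keepdims=True)) / (X.std(axis=1, keepdims=True) * np.sqrt(n))
        iu = np.triu_indices(m, 1)
        obs = float(np.abs(Zs @ Zs.T)[iu].mean())
        # all permutations in one batch: rows permuted independently per draw
        idx = rng.permuted(np.tile(np.arange(n), (n_perm * m, 1)), axis=1).reshape(n_perm, m, n)
        Zp = Zs[np.arange(m)[None, :, None], idx]
        C = Zp @ Zp.transpose(0, 2, 1)
        null = np.abs(C[:, iu[0], iu[1]]).mean(axis=1)
        pval = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
        if obs > np.quantile(null, 1.0 - alpha):
            kept_modules.append(module)
            kept_rows.append(mi)
            pvals.append(pval)

    eig = moduleset.eigengenes[kept_rows] if kept_rows else np.zeros((0, len(moduleset.cell_ids)))
    return GeneModuleSet(kept_modules, eig, list(moduleset.cell_ids), pvals, dict(moduleset.params))


def significant_modules(
    norm: NormalizedMatrix,
    genes: list[str],
    params: ModuleParams = ModuleParams(),
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> GeneModuleSet:
    """Detect modules with held-out validation of their co-expression.

    Modules are detected on a ``detect_frac`` fraction of the cells and
    validated on the rest.

    With many more genes than cells, a sample correlation matrix always
    contains chance factor structure, and any branch *selected* for high
    coherence beats a gene-wise permutation null evaluated on the same
    cells. This routine therefore splits the cells in half: modules are
    detected on one half and their coherence is tested (permutation test
    of :func:`module_significance`) on the held-out half, where the
    selection bias is absent and the null is valid. Eigengenes of the
    surviving modules are recomputed on all cells.
    """
    rng = np.random.default_rng(seed)
    n = norm.n_cells
    if n < 6:
        return GeneModuleSet([], np.zeros((0, n)), list(norm.cell_ids), [], asdict(params))
    perm = rng.permutation(n)
    n_detect = max(3, min(n - 3, int(round(params.detect_frac * n))))
    half1 = [norm.cell_ids[i] for i in np.sort(perm[:n_detect])]
    half2 = [norm.cell_ids[i] for i in np.sort(perm[n_detect:])]

    detected = detect_modules(norm.subset_cells(half1), genes, params)
    if len(detected) == 0:
        return GeneModuleSet([], np.zeros((0, n)), list(norm.cell_ids), [], asdict(params))
    validated = module_significance(
        detected, norm.subset_cells(half2), n_perm=n_perm, alpha=alpha,
        seed=int(rng.integers(2**31)),
    )
    if len(validated) == 0:
        return GeneModuleSet([], np.zeros((0, n)), list(norm.cell_ids), [], asdict(params))
    eig = eigengenes(norm, validated.modules)
    return GeneModuleSet(
        validated.modules, eig, list(norm.cell_ids), list(validated.significance_p),
        asdict(params),
    )


def eigengenes(norm: NormalizedMatrix, modules: list[list[str]]) -> np.ndarray:
    """First principal component per module on z-scored log10(CPM+1).

    Rows are scaled to unit sample variance and sign-oriented so each
    eigengene correlates positively with the module's mean profile.
    Zero-variance genes are dropped with a warning.
    """
    if not modules:
        raise ValueError("modules must be nonempty")
    gidx = norm.gene_index()
    out = np.zeros((len(modules), norm.n_cells))
    for mi, module in enumerate(modules):
        X = log_cpm(norm.values[[gidx[g] for g in module]])
        sd = X.std(axis=1)
        if (sd == 0).any():
            dropped = [g for g, s in zip(module, sd) if s == 0]
            warnings.warn(f"zero-variance gene(s) dropped from module {mi}: {dropped}")
            X = X[sd > 0]
            sd = sd[sd > 0]
        if X.shape[0] == 0:
            continue
        Xz = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        _, _, vt = np.linalg.svd(Xz, full_matrices=False)
        e = vt[0]
        mean_profile = Xz.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        s = e.std(ddof=1)
        out[mi] = e / s if s > 0 else e
    return out
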