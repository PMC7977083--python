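"""Gene selection, module detection, permutation significance, eigengenes."""

import numpy as np
import pytest

from scproprio import GeneModuleSet, NormalizedMatrix
from scproprio.modules import (
    ModuleParams,
    detect_modules,
    eigengenes,
    fano_select,
    module_significance,
    significant_modules,
)


def _norm(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(values, genes, cells)


def _blocks_matrix(n_blocks=2, block_size=10, n_cells=40, noise=0.1, seed=0):
    """Planted co-expression blocks driven by orthogonal sinusoid factors,
    so cross-block correlation is ~0 by construction (CPM-scale values)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_cells)
    factors = [np.cos(2 * np.pi * (k + 1) * t / n_cells) for k in range(n_blocks)]
    rows = []
    for k in range(n_blocks):
        for _ in range(block_size):
            rows.append(10 ** (2 + factors[k] + noise * rng.standard_normal(n_cells)) - 1)
    return _norm(np.array(rows))


class TestFanoSelect:
    def test_arithmetic_and_constant_gene(self):
        norm = _norm([[0, 4], [5, 5], [1, 3]])
        # gene0: mean 2, sample variance 8, Fano 4; gene1 constant: Fano 0
        order = fano_select(norm, k=3)
        assert order[0] == "g0" and order[-1] == "g1"

    def test_k_larger_than_gene_count_warns_and_returns_all(self):
        norm = _norm([[0, 4], [1, 3]])
        with pytest.warns(UserWarning, match="returning all"):
            out = fano_select(norm, k=10)
        assert set(out) == {"g0", "g1"}

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            fano_select(_norm(np.zeros((3, 4))))

    def test_zero_mean_genes_excluded(self):
        norm = _norm([[0, 0], [1, 5]])
        assert fano_select(norm, k=2) == ["g1"]


class TestDetectModules:
    def test_two_planted_blocks_found_exactly(self):
        norm = _blocks_matrix(n_blocks=2, block_size=10, n_cells=40)
        params = ModuleParams(min_module_size=5)
        found = detect_modules(norm, list(norm.gene_ids), params)
        assert len(found) == 2
        assert sorted(map(tuple, (sorted(m) for m in found.modules))) == [
            tuple(f"g{i}" for i in range(10)),
            tuple(sorted(f"g{i}" for i in range(10, 20))),
        ]

    def test_duplicated_pair_with_min_size_two(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(2, 1, 30)
        noise = rng.lognormal(2, 1, (6, 30))
        values = np.vstack([base, base, noise])
        found = detect_modules(_norm(values), [f"g{i}" for i in range(8)],
                               ModuleParams(min_module_size=2))
        assert ["g0", "g1"] in found.modules

    def test_gene_order_invariance(self):
        norm = _blocks_matrix(seed=3)
        params = ModuleParams(min_module_size=5)
        a = detect_modules(norm, list(norm.gene_ids), params)
        rng = np.random.default_rng(0)
        shuffled = [norm.gene_ids[i] for i in rng.permutation(len(norm.gene_ids))]
        b = detect_modules(norm, shuffled, params)
        assert sorted(map(tuple, a.modules)) == sorted(map(tuple, b.modules))

    def test_independent_genes_yield_no_validated_modules(self):
        rng = np.random.default_rng(8)
        values = rng.lognormal(2, 1, (60, 60))
        norm = _norm(values)
        out = significant_modules(norm, list(norm.gene_ids), ModuleParams(), seed=1)
        assert len(out) == 0

    def test_too_few_genes_empty(self):
        norm = _blocks_matrix()
        out = detect_modules(norm, list(norm.gene_ids)[:3], ModuleParams(min_module_size=10))
        assert len(out) == 0


class TestModuleSignificance:
    def test_planted_block_retained_at_minimal_p(self):
        norm = _blocks_matrix(n_blocks=1, block_size=10, n_cells=50)
        ms = GeneModuleSet([list(norm.gene_ids)], np.zeros((1, 50)), list(norm.cell_ids))
        out = module_significance(ms, norm, n_perm=100, alpha=0.05, seed=0)
        assert len(out) == 1
        assert out.significance_p[0] == pytest.approx(1 / 101)

    def test_empty_in_empty_out(self):
        norm = _blocks_matrix()
        ms = GeneModuleSet([], np.zeros((0, norm.n_cells)), list(norm.cell_ids))
        assert len(module_significance(ms, norm, seed=0)) == 0

    def test_zero_permutations_rejected(self):
        norm = _blocks_matrix()
        ms = GeneModuleSet([list(norm.gene_ids)[:5]], np.zeros((1, norm.n_cells)), list(norm.cell_ids))
        with pytest.raises(ValueError):
            module_significance(ms, norm, n_perm=0)

    def test_noise_module_rejection_rate(self):
        """A random gene set on pure noise is retained ~alpha of the time."""
        rng = np.random.default_rng(2)
        values = rng.lognormal(2, 1, (40, 50))
        norm = _norm(values)
        retained = 0
        n_seeds = 50
        for s in range(n_seeds):
            r = np.random.default_rng(100 + s)
            genes = [norm.gene_ids[i] for i in r.choice(40, 10, replace=False)]
            ms = GeneModuleSet([genes], np.zeros((1, 50)), list(norm.cell_ids))
            retained += len(module_significance(ms, norm, n_perm=100, alpha=0.05, seed=s)) > 0
        alpha = 0.05
        assert retained / n_seeds <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_seeds)


class TestEigengenes:
    def test_identical_genes_give_common_profile(self):
        rng = np.random.default_rng(1)
        profile = rng.lognormal(2, 1, 25)
        values = np.tile(profile, (4, 1))
        norm = _norm(values)
        eig = eigengenes(norm, [list(norm.gene_ids)])
        z = np.log10(profile + 1)
        z = (z - z.mean()) / z.std(ddof=1)
        assert np.corrcoef(eig[0], z)[0, 1] == pytest.approx(1.0)

    def test_single_gene_module_is_zscored_gene(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(2, 1, (3, 20))
        norm = _norm(values)
        eig = eigengenes(norm, [["g1"]])
        z = np.log10(values[1] + 1)
        z = (z - z.mean()) / z.std(ddof=1)
        assert np.allclose(eig[0], z)

    def test_matches_independent_svd(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(2, 1, (10, 20))
        norm = _norm(values)
        eig = eigengenes(norm, [list(norm.gene_ids)])
        X = np.log10(values + 1)
        Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(Xz)  # brute-force full SVD oracle
        v = vt[0] / vt[0].std(ddof=1)
        assert min(np.abs(eig[0] - v).max(), np.abs(eig[0] + v).max()) < 1e-8

    def test_rows_unit_variance_and_oriented(self):
        norm = _blocks_matrix(n_blocks=2)
        found = detect_modules(norm, list(norm.gene_ids), ModuleParams(min_module_size=5))
        for i, module in enumerate(found.modules):
            assert found.eigengenes[i].std(ddof=1) == pytest.approx(1.0)
            gidx = norm.gene_index()
            X = np.log10(norm.values[[gidx[g] for g in module]] + 1)
            Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
            assert np.corrcoef(found.eigengenes[i], Xz.mean(axis=0))[0, 1] > 0

    def test_zero_variance_gene_dropped_with_warning(self):
        values = np.vstack([np.full(20, 7.0), np.random.default_rng(0).lognormal(2, 1, (2, 20))])
        norm = _norm(values)
        with pytest.warns(UserWarning, match="zero-variance"):
            eig = eigengenes(norm, [list(norm.gene_ids)])
        assert np.isfinite(eig).all()
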