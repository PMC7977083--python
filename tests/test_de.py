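"""Moderated differential expression, BH adjustment, and marker selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from scproprio import (
    SyntheticSpec,
    all_pairs_de,
    bh_adjust,
    moderated_de,
    select_markers,
    simulate_counts,
)
from scproprio.containers import CountMatrix
from scproprio.qc import cpm_normalize


def _counts(values, genes=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{j}" for j in range(values.shape[1])]
    return CountMatrix(values, genes, cells), cells


def _labels(cells, split):
    return pd.Series(["a" if j < split else "b" for j in range(len(cells))], index=cells)


class TestBHAdjust:
    def test_matches_textbook_stepup_on_worked_vector(self):
        # hand-worked BH step-up: adj_i = min_{j>=i} p_(j) * m / j (then rank-restored)
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        expected = np.array(
            [0.01, 0.04, 0.084, 0.084, 0.084, 0.1, 0.105714285714, 0.216, 0.216, 0.216]
        )
        assert np.allclose(bh_adjust(p), expected, atol=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        hnp.arrays(
            float,
            hnp.array_shapes(min_dims=1, max_dims=1, min_side=1, max_side=40),
            elements=st.floats(1e-12, 1.0),
        )
    )
    def test_monotone_and_bounded_below_by_raw(self, p):
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestModeratedDE:
    def test_identical_gene_has_no_signal(self):
        # genes constant across cells: identical in both clusters -> FC 0, p 1
        values = np.tile(np.array([[30], [10], [55]]), (1, 20))
        counts, cells = _counts(values)
        res = moderated_de(counts, _labels(cells, 10), ("a", "b"))
        assert np.allclose(res.table["log2_fold_change"], 0.0)
        assert (res.table["raw_p"] == 1.0).all()

    def test_requires_two_cells_per_group(self):
        counts, cells = _counts(np.random.default_rng(1).poisson(10, (5, 10)))
        with pytest.raises(ValueError, match=">= 2 cells"):
            moderated_de(counts, _labels(cells, 1), ("a", "b"))

    def test_d0_limits(self):
        """d0 -> 0 recovers the pooled t; d0 -> infinity tests against
        the common prior variance."""
        rng = np.random.default_rng(3)
        values = rng.poisson(40, (50, 30))
        counts, cells = _counts(values)
        labels = _labels(cells, 15)

        tiny = moderated_de(counts, labels, ("a", "b"), d0=1e-9).table
        X = np.log2(values / values.sum(axis=0) * 1e6 + 1.0)
        x1, x2 = X[:, :15], X[:, 15:]
        s2 = (x1.var(axis=1, ddof=1) * 14 + x2.var(axis=1, ddof=1) * 14) / 28
        t_pooled = (x1.mean(axis=1) - x2.mean(axis=1)) / np.sqrt(s2 * (2 / 15))
        assert np.allclose(tiny["t"], t_pooled, atol=1e-4)

        huge = moderated_de(counts, labels, ("a", "b"), d0=1e9).table
        s0 = np.median(s2)
        t_prior = (x1.mean(axis=1) - x2.mean(axis=1)) / np.sqrt(s0 * (2 / 15))
        assert np.allclose(huge["t"], t_prior, atol=1e-4)

    def test_planted_markers_recovered_with_high_sensitivity(self):
        spec = SyntheticSpec(
            n_genes=500, cluster_sizes=(40, 40), marker_genes_per_cluster=20,
            marker_fold_change=4.0, n_lowdepth_cells=0, n_contaminant_cells=0, seed=4,
        )
        counts, truth = simulate_counts(spec)
        res = moderated_de(counts, truth.cell_labels, ("cluster1", "cluster2"))
        sig = res.de_genes(fdr=0.05)
        planted = {g for v in truth.marker_map.values() for g in v}
        sensitivity = len(planted & set(sig.index)) / len(planted)
        assert sensitivity >= 0.9


class TestSelectMarkers:
    def test_binary_on_off_gene_is_marker(self):
        rng = np.random.default_rng(5)
        n = 40
        values = rng.poisson(30, (30, n))
        # gene 0: detected in 90% of cluster a cells, ~5% elsewhere, strongly DE
        on = (rng.uniform(size=20) < 0.9) * rng.poisson(200, 20)
        off = (rng.uniform(size=20) < 0.05) * rng.poisson(5, 20)
        values[0] = np.concatenate([on, off])
        counts, cells = _counts(values)
        labels = _labels(cells, 20)
        de = all_pairs_de(counts, labels)
        table = select_markers(de, cpm_normalize(counts), labels, min_pairs=1)
        assert "g0" in table.table.index
        assert table.table.loc["g0", "clusters_on"] == ["a"]

    def test_housekeeping_gene_excluded(self):
        rng = np.random.default_rng(6)
        values = rng.poisson(100, (20, 30))
        counts, cells = _counts(values)
        labels = _labels(cells, 15)
        de = all_pairs_de(counts, labels)
        table = select_markers(de, cpm_normalize(counts), labels, min_pairs=0)
        assert len(table.table) == 0  # everything detected everywhere: no off cluster

    def test_fewer_than_two_clusters_is_error(self):
        counts, cells = _counts(np.random.default_rng(7).poisson(10, (5, 10)))
        labels = pd.Series(["a"] * 10, index=cells)
        with pytest.raises(ValueError, match="2 clusters"):
            select_markers({}, cpm_normalize(counts), labels)

    def test_planted_marker_map_recovered(self, qc_filtered):
        kept, _, truth = qc_filtered
        labels = truth.cell_labels.reindex(kept.cell_ids)
        de = all_pairs_de(kept, labels)
        table = select_markers(de, cpm_normalize(kept), labels)
        found = set(table.table.index)
        planted = {g for v in truth.marker_map.values() for g in v}
        precision = len(found & planted) / max(len(found), 1)
        assert precision >= 0.9
        # on-clusters point at the home cluster
        for cluster, genes in truth.marker_map.items():
            for g in set(genes) & found:
                assert table.table.loc[g, "clusters_on"] == [cluster]
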