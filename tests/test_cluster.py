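"""Recursive splitting, merge-by-DE-score, and full iterative clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from scproprio import (
    ClusteringConfig,
    SyntheticSpec,
    iter_cluster,
    merge_by_score,
    pair_merge_score,
    simulate_counts,
    split_once,
)
from scproprio.config import DEConfig
from scproprio.containers import CountMatrix


def _blob_eigengenes(sizes, seed=0, sep=4.0):
    """Cells drawn around well-separated centers in a 3-eigengene space."""
    rng = np.random.default_rng(seed)
    cols = []
    for k, n in enumerate(sizes):
        center = np.zeros(3)
        center[k % 3] = sep * (1 if k < 3 else -1)
        cols.append(center[:, None] + rng.standard_normal((3, n)) * 0.3)
    return np.hstack(cols)


class TestSplitOnce:
    def test_two_blobs_recovered(self):
        eig = _blob_eigengenes([20, 20])
        labels = split_once(eig, min_cluster_size=4, k_max=2)
        truth = np.repeat([0, 1], 20)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_size_guard_returns_single_cluster(self):
        eig = _blob_eigengenes([3, 2])
        labels = split_once(eig, min_cluster_size=4)
        assert (labels == 0).all()

    def test_deterministic(self):
        eig = _blob_eigengenes([15, 15, 12], seed=5)
        a = split_once(eig)
        b = split_once(eig)
        assert np.array_equal(a, b)

    def test_small_clusters_reabsorbed(self):
        eig = _blob_eigengenes([20, 20])
        labels = split_once(eig, min_cluster_size=4, k_max=4)
        _, sizes = np.unique(labels, return_counts=True)
        assert (sizes >= 4).all()


def _two_group_counts(n_de=10, n_genes=200, n_cells=40, seed=0, fold=8.0):
    """Two equal groups; the first n_de genes are strongly DE.

    The fold change is kept moderate so the boosted genes do not distort
    the CPM of the remaining genes past the log2FC filter."""
    rng = np.random.default_rng(seed)
    base = rng.poisson(50, (n_genes, n_cells))
    labels = np.array(["a"] * (n_cells // 2) + ["b"] * (n_cells // 2))
    values = base.copy()
    values[:n_de, labels == "a"] = rng.poisson(50 * fold, (n_de, n_cells // 2))
    cells = [f"c{j}" for j in range(n_cells)]
    counts = CountMatrix(values, [f"g{i}" for i in range(n_genes)], cells)
    return counts, pd.Series(labels, index=cells)


class TestPairMergeScore:
    def test_capped_score_for_extreme_genes(self):
        counts, labels = _two_group_counts(n_de=10)
        score = pair_merge_score(counts, labels, ("a", "b"))
        # each of the 10 planted genes hits the raw-p cap of 20 exactly
        assert score == pytest.approx(200)

    def test_identical_expression_scores_zero(self):
        counts, labels = _two_group_counts(n_de=0)
        assert pair_merge_score(counts, labels, ("a", "b")) == 0.0

    def test_tiny_cluster_warns_and_scores_zero(self):
        counts, labels = _two_group_counts()
        labels.iloc[1:] = "b"
        with pytest.warns(UserWarning, match="< 2 cells"):
            assert pair_merge_score(counts, labels, ("a", "b")) == 0.0


class TestMergeByScore:
    def _labels(self, mapping):
        return pd.Series({f"c{i}": lab for i, lab in enumerate(mapping)})

    def test_score_just_below_threshold_merges(self):
        labels = self._labels(["a"] * 5 + ["b"] * 5)
        merged, merges = merge_by_score(labels, {("a", "b"): 99.9}, threshold=100)
        assert merged.nunique() == 1 and len(merges) == 1

    def test_score_at_threshold_kept(self):
        labels = self._labels(["a"] * 5 + ["b"] * 5)
        merged, merges = merge_by_score(labels, {("a", "b"): 100.0}, threshold=100)
        assert merged.nunique() == 2 and not merges

    def test_three_clusters_with_rescoring(self):
        labels = self._labels(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        scores = {("a", "b"): 50.0, ("a", "c"): 500.0, ("b", "c"): 500.0}
        merged, _ = merge_by_score(
            labels, scores, threshold=100, rescore=lambda lab, pair: 150.0
        )
        assert merged.nunique() == 2

    def test_single_cluster_unchanged(self):
        labels = self._labels(["a"] * 6)
        merged, merges = merge_by_score(labels, {}, threshold=100)
        assert merged.equals(labels) and not merges


class TestIterCluster:
    def test_homogeneous_data_one_leaf(self, homogeneous_counts):
        counts, _ = homogeneous_counts
        assignment = iter_cluster(counts, ClusteringConfig(), seed=0)
        assert assignment.n_clusters() == 1

    def test_minor_flag_below_fifteen_cells(self):
        spec = SyntheticSpec(
            n_genes=300, cluster_sizes=(12,), marker_genes_per_cluster=0,
            n_lowdepth_cells=0, n_contaminant_cells=0, seed=2,
        )
        counts, _ = simulate_counts(spec)
        assignment = iter_cluster(counts, ClusteringConfig(), seed=0)
        assert all(assignment.minor_flags.values())

    def test_deterministic_given_seed(self, qc_filtered):
        kept, _, _ = qc_filtered
        a = iter_cluster(kept, ClusteringConfig(), seed=4)
        b = iter_cluster(kept, ClusteringConfig(), seed=4)
        assert a.labels.equals(b.labels)

    def test_planted_clusters_recovered(self, qc_filtered):
        kept, _, truth = qc_filtered
        assignment = iter_cluster(kept, ClusteringConfig(), seed=0)
        truth_labels = truth.cell_labels.reindex(kept.cell_ids)
        ari = adjusted_rand_score(truth_labels, assignment.labels.reindex(kept.cell_ids))
        assert assignment.n_clusters() == 5
        assert ari >= 0.95

    def test_tree_leaves_partition_cells(self, qc_filtered):
        kept, _, _ = qc_filtered
        assignment = iter_cluster(kept, ClusteringConfig(), seed=1)
        assert set(assignment.labels.index) == set(kept.cell_ids)
        assert assignment.labels.notna().all()
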