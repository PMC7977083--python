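"""Generator contracts: planted structure, determinism, distributional checks."""

from dataclasses import replace

import numpy as np
import pytest

from scproprio import SyntheticSpec, simulate_counts, simulate_timecourse
from scproprio.modules import log_cpm
from scproprio.qc import cpm_normalize


def test_cluster_proportions_match_design():
    spec = SyntheticSpec(
        cluster_sizes=(51, 31, 84), n_lowdepth_cells=0, n_contaminant_cells=0, seed=3
    )
    counts, truth = simulate_counts(spec)
    assert counts.n_cells == 166
    sizes = truth.cell_labels.value_counts()
    assert sizes["cluster1"] == 51 and sizes["cluster2"] == 31 and sizes["cluster3"] == 84


def test_truth_covers_cells_and_markers_disjoint(default_fixture):
    counts, truth = default_fixture
    assert list(truth.cell_labels.index) == counts.cell_ids
    all_markers = [g for v in truth.marker_map.values() for g in v]
    assert len(all_markers) == len(set(all_markers))


def test_same_seed_bit_identical_different_seed_not():
    spec = SyntheticSpec(seed=42)
    a, _ = simulate_counts(spec)
    b, _ = simulate_counts(spec)
    assert np.array_equal(a.values, b.values)
    c, _ = simulate_counts(replace(spec, seed=43))
    assert not np.array_equal(a.values, c.values)


def test_poisson_limit_fano_near_one():
    """dispersion 0 with constant depth degenerates to Poisson: Fano ~ 1."""
    spec = SyntheticSpec(
        n_genes=1000,
        cluster_sizes=(500,),
        marker_genes_per_cluster=0,
        marker_fold_change=1.0,
        nb_dispersion=0.0,
        libsize_lognormal_sigma=0.0,
        n_lowdepth_cells=0,
        n_contaminant_cells=0,
        seed=9,
    )
    counts, _ = simulate_counts(spec)
    x = counts.values.astype(float)
    means = x.mean(axis=1)
    fano = x.var(axis=1, ddof=1)[means > 0] / means[means > 0]
    assert 0.9 <= fano.mean() <= 1.1


def test_marker_means_converge_to_specified_rates():
    spec = SyntheticSpec(
        n_genes=500,
        cluster_sizes=(600,),
        marker_genes_per_cluster=10,
        marker_fold_change=4.0,
        libsize_lognormal_sigma=0.2,
        n_lowdepth_cells=0,
        n_contaminant_cells=0,
        seed=5,
    )
    counts, truth = simulate_counts(spec)
    # expected mean count = E[libsize] x (gene rate / program total rate)
    n_markers = 10
    n_plain = spec.n_genes - n_markers - 3
    total_rate = n_markers * 4.0 + n_plain * 1.0
    e_lib = np.exp(spec.libsize_lognormal_mu + spec.libsize_lognormal_sigma**2 / 2)
    expected_marker = e_lib * 4.0 / total_rate
    gidx = counts.gene_index()
    obs = counts.values[[gidx[g] for g in truth.marker_map["cluster1"]]].mean()
    assert abs(obs - expected_marker) / expected_marker < 0.05


def test_lowdepth_cells_separate_cleanly(default_fixture):
    counts, truth = default_fixture
    detected = (counts.values > 0).sum(axis=0)
    by_cell = dict(zip(counts.cell_ids, detected))
    for c in truth.flagged_lowdepth:
        assert by_cell[c] < 2000
    normal = set(counts.cell_ids) - set(truth.flagged_lowdepth)
    assert all(by_cell[c] >= 2000 for c in normal)


@pytest.mark.parametrize(
    "bad_spec",
    [
        dict(cluster_sizes=()),
        dict(marker_fold_change=0.5),
        dict(nb_dispersion=-1.0),
        dict(n_genes=50),  # too small for markers + contaminant genes
    ],
)
def test_invalid_specs_rejected(bad_spec):
    with pytest.raises(ValueError):
        simulate_counts(replace(SyntheticSpec(), **bad_spec))


def _stage_specs(n, seed=11):
    base = SyntheticSpec(
        n_genes=600,
        cluster_sizes=(60, 60),
        marker_genes_per_cluster=10,
        n_lowdepth_cells=0,
        n_contaminant_cells=0,
    )
    return [replace(base, seed=seed + i) for i in range(n)]


def _mean_marker_corr(matrix, truth):
    norm = cpm_normalize(matrix)
    gidx = norm.gene_index()
    vals = []
    for genes in truth.marker_map.values():
        X = log_cpm(norm.values[[gidx[g] for g in genes]])
        sd = X.std(axis=1)
        X = X[sd > 0]
        if X.shape[0] < 2:
            continue
        r = np.corrcoef(X)
        vals.append(np.abs(r[np.triu_indices(X.shape[0], 1)]).mean())
    return float(np.mean(vals))


def test_timecourse_correlation_increases_with_decay_half():
    stages = simulate_timecourse(_stage_specs(4), coexpression_decay=0.5)
    corr = [_mean_marker_corr(m, t) for m, t in stages]
    assert all(a < b for a, b in zip(corr, corr[1:]))


def test_timecourse_decay_one_keeps_design_identical():
    specs = _stage_specs(3, seed=20)
    same_seed = [replace(s, seed=20) for s in specs]
    stages = simulate_timecourse(same_seed, coexpression_decay=1.0)
    ref, _ = simulate_counts(replace(specs[0], seed=20))
    for matrix, _truth in stages:
        assert np.array_equal(matrix.values, ref.values)


def test_timecourse_decay_zero_removes_structure_early():
    stages = simulate_timecourse(_stage_specs(3, seed=30), coexpression_decay=0.0)
    early = _mean_marker_corr(*stages[0])
    adult = _mean_marker_corr(*stages[-1])
    assert early < 0.1 < adult


def test_timecourse_input_validation():
    specs = _stage_specs(2)
    with pytest.raises(ValueError):
        simulate_timecourse(specs, coexpression_decay=1.5)
    with pytest.raises(ValueError):
        simulate_timecourse(specs[:1], coexpression_decay=0.5)
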