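import warnings

import numpy as np
import pandas as pd
import pytest

from scproprio import (
    ClusteringConfig,
    CountMatrix,
    SyntheticSpec,
    simulate_counts,
)
from scproprio.qc import cpm_normalize, filter_cells, qc_metrics


@pytest.fixture(scope="session")
def default_fixture():
    """The default benchmark dataset: 166 planted cells (51/31/28/28/28),
    10 low-depth and 8 contaminated cells, seed 0."""
    counts, truth = simulate_counts(SyntheticSpec(seed=0))
    return counts, truth


@pytest.fixture(scope="session")
def qc_filtered(default_fixture):
    counts, truth = default_fixture
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = qc_metrics(counts)
        kept, removed = filter_cells(counts, report)
    return kept, removed, truth


@pytest.fixture(scope="session")
def homogeneous_counts():
    """One cluster, no markers, no QC outliers: pure negative-binomial noise."""
    spec = SyntheticSpec(
        seed=7,
        n_genes=2000,
        cluster_sizes=(80,),
        marker_genes_per_cluster=0,
        n_lowdepth_cells=0,
        n_contaminant_cells=0,
    )
    counts, truth = simulate_counts(spec)
    return counts, truth


@pytest.fixture
def tiny_counts():
    """Hand-sized 4-gene x 3-cell matrix for arithmetic checks."""
    values = np.array(
        [
            [5, 0, 0],
            [45, 2, 0],
            [0, 8, 0],
            [0, 0, 0],
        ]
    )
    return CountMatrix(values, ["gA", "gB", "gC", "gD"], ["c1", "c2", "c3"])


@pytest.fixture(scope="session")
def fast_clustering_config():
    return ClusteringConfig()


def planted_labels(truth, cell_ids) -> pd.Series:
    return truth.cell_labels.reindex(cell_ids)
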