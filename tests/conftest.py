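import numpy as np
import pytest

import regpattern as rp


def make_cells(counts, clusters=None, genes=None, cells=None, normalized=False):
    """Small CellMatrix from a dense array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cm = rp.CellMatrix(
        counts=counts,
        cell_ids=cells or [f"cell{i}" for i in range(n_cells)],
        gene_ids=genes or [f"g{j}" for j in range(n_genes)],
        cluster_labels=np.asarray(clusters if clusters is not None else ["c0"] * n_cells, dtype=object),
    )
    if normalized:
        rp.normalize(cm)
    return cm


def random_distance(n, rng):
    m = rng.uniform(0, 1, size=(n, n))
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0.0)
    return rp.PairwiseDistance(d=d, cluster_ids=[f"L{i:02d}" for i in range(n)])


@pytest.fixture(scope="session")
def small_study():
    """12 clusters, one planted pair per pattern, profile level only."""
    truth = rp.SyntheticTruth.study(seed=7, n_clusters=12, pairs_per_pattern=1)
    means, catalog = rp.generate_cluster_means(truth)
    return truth, means, catalog


@pytest.fixture(scope="session")
def small_study_cells(small_study):
    truth, means, catalog = small_study
    truth = rp.SyntheticTruth.study(
        seed=7, n_clusters=12, pairs_per_pattern=1, cells_per_cluster=60
    )
    cells = rp.generate_counts(means, truth)
    rp.normalize(cells)
    return truth, means, catalog, cells


@pytest.fixture(scope="session")
def study_pipeline_runs():
    """Full-pipeline runs of the standard planted study over 20 seeds.

    Shared by the recovery and robustness acceptance checks so the heavy
    generation happens once.
    """
    runs = []
    for seed in range(20):
        truth = rp.SyntheticTruth.study(seed=seed)
        means, catalog = rp.generate_cluster_means(truth)
        cells = rp.generate_counts(means, truth)
        cfg = rp.AnalysisConfig(seed=seed)
        results, _ = rp.run_pipeline(cfg, cells, catalog, use_qc=False, use_hvg=False)
        runs.append((truth, results))
    return runs
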