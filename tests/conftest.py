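"""Shared fixtures: small simulated datasets and pipeline intermediates."""

from __future__ import annotations

import numpy as np
import pytest

from mstraj import (
    QcThresholds,
    TrajectoryConfig,
    cell_distance,
    consensus_mst,
    correlation_filter_genes,
    detect_modules,
    normalize,
    qc_filter_cells,
    select_modules,
    simulate_trajectory,
)
from mstraj.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def default_sim():
    """Default 200-cell synthetic dataset with truth."""
    return simulate_trajectory(TrajectoryConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """Small low-noise dataset for fast unit tests."""
    cfg = TrajectoryConfig(n_cells=100, n_genes=150, seed=7, noise=0.05,
                           dropout_rate=0.02)
    return simulate_trajectory(cfg)


@pytest.fixture(scope="session")
def small_filtered(small_sim):
    """Normalized, gene-filtered version of the small dataset."""
    m, truth = small_sim
    m, _ = qc_filter_cells(m, QcThresholds(min_total_counts=1))
    norm = normalize(m)
    kept = correlation_filter_genes(norm)
    return norm.subset_genes(kept), truth


@pytest.fixture(scope="session")
def small_graph(small_filtered):
    """Consensus graph + selected modules on the small dataset."""
    f, truth = small_filtered
    ms = select_modules(detect_modules(f))
    genes = ms.selected_genes()
    d = cell_distance(f, genes)
    g = consensus_mst(d, n_trees=100, mode="gene_resample", seed=3,
                      matrix=f, genes=genes)
    return g, ms, f, truth


@pytest.fixture()
def toy_matrix():
    """3 genes x 4 cells integer counts with names."""
    values = np.array([
        [0, 2, 4, 1],
        [5, 0, 3, 2],
        [1, 1, 1, 9],
    ], dtype=float)
    return ExpressionMatrix(values, ["gA", "gB", "gC"],
                            ["c1", "c2", "c3", "c4"], layer="counts")


def marker_genes(filtered, truth, module):
    """Module-member genes of `module` still present in the filtered matrix."""
    mod = truth.module_of_gene
    return [g for g in filtered.gene_ids if mod.get(g) == module]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
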