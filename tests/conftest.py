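"""Shared fixtures: one default synthetic aging dataset and its pipeline
products, computed once per session and reused by the downstream tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mammaclock import qc, scoring, trajectory
from mammaclock.simulate import SimulationConfig, generate_aging_dataset

DEFAULT_SEED = 0
TRUE_BOUNDARIES = (0.25, 0.55, 0.85)


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions: 4 age groups x 200 cells, 1500 genes."""
    adata, truth = generate_aging_dataset(SimulationConfig(seed=DEFAULT_SEED))
    return adata, truth


@pytest.fixture(scope="session")
def normalized(default_dataset):
    adata, truth = default_dataset
    filtered = qc.filter_cells_and_genes(adata)
    return qc.normalize(filtered), truth


@pytest.fixture(scope="session")
def cycle_call(normalized):
    norm, truth = normalized
    log_tpm = scoring.counts_to_log2_tpm(norm)
    return scoring.call_cell_cycle(log_tpm, truth.phase_gene_table)


@pytest.fixture(scope="session")
def trajectory_run(normalized, cycle_call):
    """Pseudotime, gene test, curves, clusters and states on the default data."""
    norm, truth = normalized
    pt, gene_table, curves, clusters, states = trajectory.run_trajectory_stages(
        norm, cell_cycle_scores=cycle_call.z_scores
    )
    return {
        "norm": norm,
        "truth": truth,
        "pseudotime": pt,
        "gene_table": gene_table,
        "curves": curves,
        "clusters": clusters,
        "states": states,
    }


@pytest.fixture(scope="session")
def truth_frames(default_dataset):
    """Ground-truth per-cell series indexed by barcode."""
    adata, truth = default_dataset
    idx = adata.obs_names
    return {
        "t_true": pd.Series(truth.t_true, index=idx),
        "state_true": pd.Series(truth.state_true, index=idx),
        "phase_true": pd.Series(truth.phase_true, index=idx),
        "is_contaminant": pd.Series(truth.is_contaminant, index=idx),
        "pattern_true": pd.Series(truth.pattern_true, index=adata.var_names),
    }
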