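"""Shared fixtures: a small synthetic cohort with planted structure."""

import numpy as np
import pandas as pd
import anndata as ad
import pytest

from cellprograms import simulate as sim
from cellprograms import io_qc


@pytest.fixture(scope="session")
def small_config():
    """8 cell types, 3 programs x 4 samples, one planted LR interaction."""
    return sim.SyntheticConfig(
        n_programs=3,
        samples_per_program=4,
        cell_types=[f"T{i}" for i in range(8)],
        n_genes=200,
        cells_per_sample=(400, 400),
        markers_per_type=5,
        marker_fold=4.0,
        baseline_mean=1.0,
        dispersion=2.0,
        planted_lr=[("g0100", "g0101", "T0", "T1", 8.0)],
        cnv_clusters=4,
        cnv_diversity=1.0,
        seed=20,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sim.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_adata(small_config, small_cohort):
    cells, _ = small_cohort
    adata = sim.generate_expression(small_config, cells)
    return io_qc.normalize_log1p(adata)


def make_adata(matrix, cell_ids=None, genes=None, normalize=True):
    """Dense matrix -> AnnData with the package's normalized layer."""
    X = np.asarray(matrix, dtype=float)
    cell_ids = cell_ids or [f"c{i}" for i in range(X.shape[0])]
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    if normalize:
        adata = io_qc.normalize_log1p(adata)
    return adata


def make_cells(cell_ids, sample_ids, level1, **extra):
    table = pd.DataFrame(
        {"cell_id": cell_ids, "sample_id": sample_ids, "level1": level1}
    )
    for k, v in extra.items():
        table[k] = v
    return table
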