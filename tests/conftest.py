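import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from vncatlas.datamodel import ExpressionDataset, GeneSetCatalog
from vncatlas.preprocess import log_normalize
from vncatlas.simulate import SimConfig, generate


def make_dataset(counts, gene_symbols=None, cell_ids=None) -> ExpressionDataset:
    """Small dense-array helper: counts is cells x genes."""
    counts = np.asarray(counts)
    n, g = counts.shape
    return ExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids or [f"c{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
        gene_symbols=gene_symbols or [f"g{j}" for j in range(g)],
    )


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """3 cells x 4 genes with hand-checkable counts."""
    return make_dataset(
        [[10, 0, 5, 0], [0, 3, 1, 2], [7, 7, 0, 0]],
        gene_symbols=["VAChT", "GAT", "VGlut", "Vmat"],
    )


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic dataset shared across tests."""
    ds, truth = generate(SimConfig(n_cells=1000, seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def sim_lognorm(sim_default):
    ds, truth = sim_default
    ds = ds.copy()
    log_normalize(ds)
    return ds, truth
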