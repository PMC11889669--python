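import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from uveitis_sc import synthetic_data as synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-patient paired cohort small enough for fast unit tests."""
    cfg = synth.CohortConfig(
        n_patients=2,
        cells_per_eye_sample=500,
        cells_per_blood_sample=1000,
        n_genes=400,
        n_antigen_clones=5,
        antigen_clone_size_range=(5, 12),
        seed=11,
    )
    return synth.generate_cohort(cfg)


def make_adata(X, gene_names=None, cell_names=None, **obs_cols):
    """Small dense-counts AnnData for toy tests."""
    X = np.asarray(X)
    n, g = X.shape
    genes = gene_names or [f"G{j}" for j in range(g)]
    cells = cell_names or [f"c{i}" for i in range(n)]
    obs = pd.DataFrame(obs_cols, index=cells) if obs_cols else pd.DataFrame(index=cells)
    return ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=pd.DataFrame(index=genes))


@pytest.fixture
def toy_adata_factory():
    return make_adata
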