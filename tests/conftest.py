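import numpy as np
import pandas as pd
import pytest

from otoconv import preprocess as pre
from otoconv import synthetic as syn


@pytest.fixture(scope="session")
def default_dataset():
    """The default well-separated 7x100 preset."""
    return syn.gen_umi_dataset(syn.default_sim_config(seed=1))


@pytest.fixture(scope="session")
def preprocessed(default_dataset):
    params = pre.PreprocessParams()
    filtered = pre.filter_cells_by_library_size(default_dataset, params)
    data = pre.downsample_to_reference_depth(filtered, seed=1).dataset
    hvg, _ = pre.select_hvg(data, params)
    return data, hvg


@pytest.fixture(scope="session")
def continuum_dataset():
    """600-cell SC1 -> cHC3 conversion-continuum preset."""
    return syn.gen_umi_dataset(syn.continuum_sim_config(seed=2))


@pytest.fixture(scope="session")
def continuum_preprocessed(continuum_dataset):
    params = pre.PreprocessParams()
    filtered = pre.filter_cells_by_library_size(continuum_dataset, params)
    return pre.downsample_to_reference_depth(filtered, seed=2).dataset


@pytest.fixture(scope="session")
def bulk_truth():
    return syn.default_bulk_truth(seed=3)


@pytest.fixture(scope="session")
def bulk_eset(bulk_truth):
    from otoconv import bulk as bk
    table = syn.gen_bulk_dataset(bulk_truth, seed=3)
    return bk.BulkExpressionSet.from_table(table, bulk_truth.sample_sheet())


@pytest.fixture(scope="session")
def qpcr_truth(bulk_truth):
    return syn.default_qpcr_truth(bulk_truth, seed=3)


@pytest.fixture(scope="session")
def qpcr_plate(qpcr_truth):
    plate_df, dilution = syn.gen_qpcr_plate(qpcr_truth, seed=3)
    return plate_df, dilution


def toy_dataset(counts, samples=None, populations=None, gene_names=None,
                special=None):
    """Small hand-built UmiDataset for unit tests."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = gene_names or [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame({
        "sample": samples or ["s1"] * n_cells,
        "condition": ["cond"] * n_cells,
        "true_population": populations or ["P"] * n_cells,
        "true_latent": np.full(n_cells, np.nan),
    }, index=pd.Index(cells, name="cell_id"))
    return syn.UmiDataset(counts, pd.Index(genes), pd.Index(cells), meta,
                          special or {})
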