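import numpy as np
import pytest

from sdmeta import harmonize, synthdata


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded multi-study simulation shared across tests."""
    cfg = synthdata.SimConfig(n_genes=400, seed=11)
    truth, tables, meta = synthdata.simulate_contrast_tables(cfg)
    return cfg, truth, tables, meta


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    """Gene x contrast effect matrix harmonized from the small simulation."""
    _, _, tables, meta = small_sim
    gene_effects = {cid: harmonize.collapse_to_gene(tab) for cid, tab in tables.items()}
    return harmonize.align_and_filter(gene_effects, meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
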