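import numpy as np
import pandas as pd
import pytest

from teadsig import ExpressionMatrix, GeneSet, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240220)


@pytest.fixture
def small_matrix(rng):
    """12 genes x 8 samples of lognormal-ish TPM values."""
    vals = np.round(np.exp2(rng.normal(4, 2, size=(12, 8))) - 1.0, 4).clip(0)
    genes = [f"GENE{i:02d}" for i in range(1, 13)]
    samples = [f"S{i}" for i in range(1, 9)]
    meta = pd.DataFrame(
        {"phenotype_label": ["a"] * 4 + ["b"] * 4, "lineage": "test"},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), "tpm", meta)


@pytest.fixture
def toy_geneset():
    return GeneSet("TOY", "toy set", ("GENE01", "GENE03", "GENE05"))


@pytest.fixture
def sim_config():
    """Down-scaled generator config for fast unit tests."""
    return SimConfig(seed=7, n_genes=300, n_samples_per_group=10, n_cell_lines=30,
                     n_dependent=8, n_tumors=120)
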