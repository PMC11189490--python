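import numpy as np
import pandas as pd
import pytest

from dgfate import (
    CONTROL,
    TBI,
    LineageSpec,
    NoiseConfig,
    SplicedUnsplicedDataset,
    default_gene_programs,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_lineage() -> LineageSpec:
    return LineageSpec(
        cells_per_condition={CONTROL: 300, TBI: 300},
        fate_bias_by_condition={CONTROL: 0.5, TBI: 0.75},
    )


@pytest.fixture(scope="session")
def small_dataset(small_lineage) -> SplicedUnsplicedDataset:
    programs = default_gene_programs(small_lineage, n_genes=60, seed=7)
    return simulate_dataset(small_lineage, programs, noise=NoiseConfig(), seed=7)


def make_dataset(spliced, unspliced, embedding=None, gene_ids=None, populations=None,
                 conditions=None):
    """Hand-rolled tiny dataset for oracle tests."""
    spliced = np.asarray(spliced)
    unspliced = np.asarray(unspliced)
    n_genes, n_cells = spliced.shape
    if embedding is None:
        embedding = np.c_[np.arange(n_cells, dtype=float), np.zeros(n_cells)]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if populations is None:
        populations = ["P"] * n_cells
    if conditions is None:
        conditions = [CONTROL] * n_cells
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "condition": conditions,
            "population": populations,
            "animal": ["A1"] * n_cells,
        }
    )
    return SplicedUnsplicedDataset(
        spliced=spliced,
        unspliced=unspliced,
        cell_meta=meta,
        embedding=np.asarray(embedding, dtype=float),
        gene_meta=pd.DataFrame({"gene_id": gene_ids}),
    )
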