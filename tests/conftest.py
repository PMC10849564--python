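import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from devtraj.core import CellTable
from devtraj.ladder import AgeLadder


def make_table(counts, ages, ladder=None, *, sample_ids=None, sexes=None,
               genotypes=None, cell_types=None, regions=None, gene_ids=None):
    """Build a small CellTable from a dense genes × cells array."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if ladder is None:
        labels = tuple(dict.fromkeys(ages))
        if len(labels) == 1:  # a ladder needs ≥ 2 rungs
            labels = ("E16",) + labels if labels[0] != "E16" else labels + ("P65",)
        ladder = AgeLadder(labels)
    meta = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n_cells)],
        "sample_id": sample_ids if sample_ids is not None else ["s0"] * n_cells,
        "age": list(ages),
        "sex": sexes if sexes is not None else ["F"] * n_cells,
        "genotype": genotypes if genotypes is not None else ["WT"] * n_cells,
        "cell_type": cell_types if cell_types is not None else ["t0"] * n_cells,
        "region": regions if regions is not None else ["r0"] * n_cells,
    })
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    return CellTable(counts=sp.csr_matrix(counts), gene_ids=gene_ids,
                     cell_meta=meta, ladder=ladder)


@pytest.fixture
def six_age_ladder():
    return AgeLadder(("P0", "P4", "P10", "P18", "P28", "P65"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
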