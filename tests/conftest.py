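import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from clonofate import simulate
from clonofate.core import CellMatrix, ClonotypeTable


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-archetype cohort: expanded clones (5-15 cells), 45 clones."""
    rng = np.random.default_rng(4242)
    archetypes = simulate.default_archetypes(n_clones=15)
    for spec in archetypes:
        spec.sizes = rng.integers(5, 16, size=spec.n_clones).tolist()
    return simulate.simulate_cohort(
        n_per_fate=300, n_naive=100, archetypes=archetypes, seed=42
    )


@pytest.fixture(scope="session")
def cd4cd8_matrix():
    return simulate.simulate_cd4cd8(simulate.CD4CD8Config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_cell_matrix(counts, cell_ids=None, gene_ids=None, **kw) -> CellMatrix:
    counts = np.asarray(counts)
    n, g = counts.shape
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids if cell_ids is not None else [f"c{i}" for i in range(n)],
        gene_ids=gene_ids if gene_ids is not None else [f"g{j}" for j in range(g)],
        **kw,
    )


def make_clonotypes(mapping: dict) -> ClonotypeTable:
    """mapping: clone_id -> list of barcodes."""
    rows = [(bc, cid) for cid, bcs in mapping.items() for bc in bcs]
    df = pd.DataFrame(rows, columns=["barcode", "clone_id"]).set_index("barcode")
    return ClonotypeTable(assignments=df)
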