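import numpy as np
import pytest
import scipy.sparse as sp

from spotcoloc import SpotMatrix
from spotcoloc.graph import SpatialGraph


def make_spot_matrix(counts, coords=None, condition=None, gene_ids=None, barcodes=None):
    """Build a SpotMatrix from a dense array with generated identifiers."""
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"bc{i}" for i in range(n_spots)]
    return SpotMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.asarray(gene_ids, dtype=object),
        gene_names=np.asarray(gene_ids, dtype=object),
        barcodes=np.asarray(barcodes, dtype=object),
        coords=coords,
        condition=condition,
    )


@pytest.fixture
def triangle_graph():
    """The unique triangulation of 3 non-collinear points."""
    return SpatialGraph(n_spots=3, edges=[(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
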