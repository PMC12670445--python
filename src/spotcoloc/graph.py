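"""Delaunay spot-adjacency graph and neighborhood averaging.

The neighbor graph is parameter-free: edges are exactly the triangle edges of
a Delaunay triangulation of the 2D spot coordinates. A deterministic
micro-jitter (1e-9 of the bounding-box diagonal, fixed seed) is applied before
triangulating so near-degenerate (cocircular) configurations resolve
reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay

from .errors import (
    CollinearPointsError,
    DuplicatePointsError,
    GraphError,
    IsolatedVertexError,
    TooFewPointsError,
)

__all__ = [
    "SpatialGraph",
    "build_delaunay_graph",
    "neighborhood_average",
    "degree_summary",
    "write_edges",
    "read_edges",
]

logger = logging.getLogger(__name__)

JITTER_SCALE = 1e-9
JITTER_SEED = 20230415


@dataclass
class SpatialGraph:
    """Undirected simple graph over spot indices ``0..n_spots-1``."""

    n_spots: int
    edges: np.ndarray  # (m, 2) int array, each row sorted, rows unique
    _adjacency: Optional[sp.csr_matrix] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if np.any(edges[:, 0] == edges[:, 1]):
                raise GraphError("self-loops are not allowed")
            if edges.min() < 0 or edges.max() >= self.n_spots:
                raise GraphError("edge index out of range")
            edges = np.sort(edges, axis=1)
            edges = np.unique(edges, axis=0)
        self.edges = edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix (CSR)."""
        if self._adjacency is None:
            if self.n_edges:
                i, j = self.edges[:, 0], self.edges[:, 1]
                data = np.ones(2 * self.n_edges)
                adj = sp.coo_matrix(
                    (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
                    shape=(self.n_spots, self.n_spots),
                )
            else:
                adj = sp.coo_matrix((self.n_spots, self.n_spots))
            self._adjacency = adj.tocsr()
        return self._adjacency

    def neighbors(self, i: int) -> np.ndarray:
        """Sorted neighbor indices of spot ``i``."""
        row = self.adjacency.getrow(i)
        return np.sort(row.indices)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adjacency[i, j])


def build_delaunay_graph(coords, jitter_seed: int = JITTER_SEED) -> SpatialGraph:
    """Build the undirected Delaunay adjacency graph of 2D points.

    Raises :class:`TooFewPointsError` (<3 points),
    :class:`DuplicatePointsError` (coincident points) or
    :class:`CollinearPointsError` (rank-deficient configuration).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise GraphError(f"coords must be (n, 2), got {coords.shape}")
    n = len(coords)
    if n < 3:
        raise TooFewPointsError(f"need >=3 points for a triangulation, got {n}")
    if len(np.unique(coords, axis=0)) != n:
        raise DuplicatePointsError("coincident points in coordinate set")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise CollinearPointsError("all points are collinear")

    span = coords.max(axis=0) - coords.min(axis=0)
    diag = float(np.hypot(*span))
    rng = np.random.default_rng(jitter_seed)
    jitter = rng.normal(scale=JITTER_SCALE * diag, size=coords.shape)
    logger.debug(
        "delaunay: jittering %d points by %.3g (seed %d)",
        n,
        JITTER_SCALE * diag,
        jitter_seed,
    )
    tri = Delaunay(coords + jitter)
    simplices = tri.simplices
    edges = np.concatenate(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
    )
    return SpatialGraph(n_spots=n, edges=edges)


def neighborhood_average(
    g: SpatialGraph, x, include_self: bool = False
) -> np.ndarray:
    """Average ``x`` over each spot's graph neighborhood.

    The focal spot is excluded by default (Delaunay adjacency has no
    self-edges); pass ``include_self=True`` to include it with weight equal
    to one neighbor.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (g.n_spots,):
        raise GraphError(f"vector length {x.shape} != n_spots {g.n_spots}")
    adj = g.adjacency
    if include_self:
        adj = adj + sp.identity(g.n_spots, format="csr")
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise IsolatedVertexError(
            f"{int((deg == 0).sum())} isolated vertices cannot be averaged"
        )
    return (adj @ x) / deg


def degree_summary(g: SpatialGraph):
    """Per-spot degrees plus a degree histogram ``{degree: count}``."""
    deg = g.degrees()
    values, counts = np.unique(deg, return_counts=True) if len(deg) else ((), ())
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    return deg, hist


def write_edges(g: SpatialGraph, barcodes, path) -> None:
    """Export as a 2-column TSV of barcodes, lexicographically ordered per row."""
    barcodes = np.asarray(barcodes, dtype=object)
    if len(barcodes) != g.n_spots:
        raise GraphError("barcode list length != n_spots")
    rows = sorted(
        tuple(sorted((barcodes[i], barcodes[j]))) for i, j in g.edges
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_edges(path, barcodes) -> SpatialGraph:
    """Import a barcode edge-list TSV back into a :class:`SpatialGraph`."""
    barcodes = np.asarray(barcodes, dtype=object)
    lookup = {bc: i for i, bc in enumerate(barcodes)}
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    try:
        edges = np.array([[lookup[a], lookup[b]] for a, b in df.itertuples(index=False)])
    except KeyError as exc:
        raise GraphError(f"edge-list barcode {exc} not in barcode set") from exc
    return SpatialGraph(n_spots=len(barcodes), edges=edges.reshape(-1, 2))
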