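"""Spatial colocalization: correlation of one gene's expression with the
neighborhood-averaged expression of another, with a permutation null.

The statistic is directional: gene A is the anchor whose per-spot expression
enters the correlation untouched; gene B is the one averaged over each spot's
Delaunay neighborhood. Significance comes from shuffling gene B's values
across spots (default 100 shuffles) and computing a one-sided empirical
p-value with an add-one pseudocount, so p is never 0 and its floor is
1/(n_perm + 1).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, rankdata

from .errors import UndefinedCorrelationError
from .graph import SpatialGraph, neighborhood_average
from .io import SpotMatrix

__all__ = [
    "ColocResult",
    "ColocMatrix",
    "coloc_score",
    "permutation_test",
    "coloc_matrix",
]

DEFAULT_N_PERM = 100
DEFAULT_ALPHA = 0.05


@dataclass
class ColocResult:
    gene_a: str
    gene_b: str
    score: float
    null_scores: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self):
        self.null_scores = np.asarray(self.null_scores, dtype=float)


@dataclass
class ColocMatrix:
    """Pairwise score/p matrices (rows = averaged genes, cols = anchor genes)."""

    row_genes: List[str]
    col_genes: List[str]
    scores: np.ndarray
    p_values: np.ndarray
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    skipped_genes: List[str] = field(default_factory=list)

    def __post_init__(self):
        shape = (len(self.row_genes), len(self.col_genes))
        self.scores = np.asarray(self.scores, dtype=float).reshape(shape)
        self.p_values = np.asarray(self.p_values, dtype=float).reshape(shape)

    @property
    def significant(self) -> np.ndarray:
        """Boolean mask: defined p-value <= alpha."""
        with np.errstate(invalid="ignore"):
            return (self.p_values <= self.alpha) & ~np.isnan(self.p_values)

    def masked_scores(self) -> np.ndarray:
        """Scores with non-significant cells set to NaN (prefiltered heatmap)."""
        out = self.scores.copy()
        out[~self.significant] = np.nan
        return out

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table with BH-adjusted p-values added."""
        rows = []
        for i, gb in enumerate(self.row_genes):
            for j, ga in enumerate(self.col_genes):
                rows.append(
                    {
                        "gene_a": ga,
                        "gene_b": gb,
                        "score": self.scores[i, j],
                        "p_value": self.p_values[i, j],
                        "n_perm": self.n_perm,
                        "seed": self.seed,
                    }
                )
        df = pd.DataFrame(rows)
        df["p_adj"] = np.nan
        defined = df["p_value"].notna()
        if defined.any():
            df.loc[defined, "p_adj"] = false_discovery_control(
                df.loc[defined, "p_value"], method="bh"
            )
        return df[["gene_a", "gene_b", "score", "p_value", "p_adj", "n_perm", "seed"]]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def coloc_score(
    x_a,
    x_b,
    g: SpatialGraph,
    method: str = "pearson",
    include_self: bool = False,
) -> float:
    """Correlation of ``x_a`` with the neighborhood average of ``x_b``.

    Not symmetric in (A, B): only B is averaged over the graph.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    nb = neighborhood_average(g, x_b, include_self=include_self)
    if np.ptp(x_a) == 0:
        raise UndefinedCorrelationError("x_a is constant; correlation undefined")
    if np.ptp(nb) == 0:
        raise UndefinedCorrelationError(
            "neighborhood-averaged x_b is constant; correlation undefined"
        )
    if method == "pearson":
        return _pearson(x_a, nb)
    if method == "spearman":
        return _pearson(rankdata(x_a), rankdata(nb))
    raise ValueError(f"unknown correlation method {method!r}")


def _pair_rng(seed: int, gene_a: str, gene_b: str) -> np.random.Generator:
    """Deterministic per-pair RNG stream derived from (seed, gene ids)."""
    digest = hashlib.blake2b(
        f"{gene_a}\x00{gene_b}".encode(), digest_size=8
    ).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")])
    )


def permutation_test(
    x_a,
    x_b,
    g: SpatialGraph,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    gene_a: str = "geneA",
    gene_b: str = "geneB",
    method: str = "pearson",
    include_self: bool = False,
) -> ColocResult:
    """Permutation test of the colocalization score.

    ``x_b`` is shuffled across spots ``n_perm`` times using an RNG stream
    derived from ``(seed, gene_a, gene_b)``; the one-sided empirical p-value
    uses the add-one pseudocount ``p = (1 + #{null >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    observed = coloc_score(x_a, x_b, g, method=method, include_self=include_self)

    rng = _pair_rng(seed, gene_a, gene_b)
    perms = np.empty((len(x_b), n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(x_b)

    if method == "pearson":
        # vectorized: neighborhood-average all permutations at once, then
        # correlate each column with x_a
        adj = g.adjacency
        deg = np.asarray(adj.sum(axis=1)).ravel()
        if include_self:
            from scipy import sparse as _sp

            adj = adj + _sp.identity(g.n_spots, format="csr")
            deg = deg + 1
        nb = (adj @ perms) / deg[:, None]
        xc = x_a - x_a.mean()
        nbc = nb - nb.mean(axis=0)
        denom = np.sqrt((xc @ xc) * (nbc * nbc).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            null_scores = np.clip((xc @ nbc) / denom, -1.0, 1.0)
    else:
        null_scores = np.array(
            [
                coloc_score(x_a, perms[:, k], g, method=method, include_self=include_self)
                for k in range(n_perm)
            ]
        )

    with np.errstate(invalid="ignore"):
        n_ge = int(np.sum(null_scores >= observed))
    p_value = (1 + n_ge) / (1 + n_perm)
    return ColocResult(
        gene_a=gene_a,
        gene_b=gene_b,
        score=observed,
        null_scores=null_scores,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
    )


def coloc_matrix(
    m: SpotMatrix,
    row_genes: Sequence[str],
    col_genes: Sequence[str],
    g: SpatialGraph,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    source: str = "normalized",
    method: str = "pearson",
) -> ColocMatrix:
    """All-pairs colocalization matrix.

    Entry (i, j) tests anchor gene ``col_genes[j]`` (gene A) against the
    neighborhood-averaged ``row_genes[i]`` (gene B). Per-pair RNG streams are
    derived from the master seed and both gene ids, so subsetting the gene
    lists leaves surviving pairs' p-values unchanged. Genes with all-zero
    expression are skipped with a warning and yield NaN cells.
    """
    row_genes = list(row_genes)
    col_genes = list(col_genes)
    expr = {}
    skipped = []
    for gene in dict.fromkeys(row_genes + col_genes):
        x = m.expression(gene, source=source)  # KeyError on unknown gene
        if np.all(x == 0):
            skipped.append(gene)
        expr[gene] = x
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} gene(s) with all-zero expression: {skipped}",
            stacklevel=2,
        )
    scores = np.full((len(row_genes), len(col_genes)), np.nan)
    p_values = np.full_like(scores, np.nan)
    for i, gb in enumerate(row_genes):
        for j, ga in enumerate(col_genes):
            if ga in skipped or gb in skipped:
                continue
            res = permutation_test(
                expr[ga],
                expr[gb],
                g,
                n_perm=n_perm,
                seed=seed,
                gene_a=ga,
                gene_b=gb,
                method=method,
            )
            scores[i, j] = res.score
            p_values[i, j] = res.p_value
    return ColocMatrix(
        row_genes=row_genes,
        col_genes=col_genes,
        scores=scores,
        p_values=p_values,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        skipped_genes=skipped,
    )
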