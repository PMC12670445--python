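"""Composition summaries from deconvolution proportions and subset labels,
plus the Wilcoxon rank-sum marker filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu, rankdata

from .errors import DataConsistencyError
from .io import SpotMatrix

__all__ = [
    "ProportionTable",
    "CompositionSummary",
    "dominant_type",
    "enriched_spots",
    "subset_frequencies",
    "marker_test",
]

DEFAULT_ENRICHMENT_THRESHOLD = 0.25
DEFAULT_LFC_THRESHOLD = 0.25
EXACT_MAX_GROUP = 10
ROW_SUM_TOL = 1e-6


@dataclass
class ProportionTable:
    """Spot-by-cell-type proportion matrix; rows sum to 1."""

    barcodes: np.ndarray
    cell_types: List[str]
    proportions: np.ndarray

    def __post_init__(self):
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.cell_types = [str(t) for t in self.cell_types]
        self.proportions = np.asarray(self.proportions, dtype=float)
        n, t = self.proportions.shape
        if len(self.barcodes) != n:
            raise DataConsistencyError("barcode count != proportion rows")
        if len(self.cell_types) != t:
            raise DataConsistencyError("cell type count != proportion columns")
        if len(set(self.cell_types)) != t:
            raise DataConsistencyError("cell type names are not unique")
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise DataConsistencyError("proportions must lie in [0, 1]")
        if n and np.any(np.abs(self.proportions.sum(axis=1) - 1.0) > ROW_SUM_TOL):
            raise DataConsistencyError("proportion rows must sum to 1")

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    def column(self, cell_type: str) -> np.ndarray:
        if cell_type not in self.cell_types:
            raise KeyError(f"unknown cell type {cell_type!r}")
        return self.proportions[:, self.cell_types.index(cell_type)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, columns=self.cell_types)
        df.insert(0, "barcode", self.barcodes)
        return df


@dataclass
class CompositionSummary:
    """Per-condition label frequencies and raw spot counts.

    ``frequencies`` and ``counts`` are condition x label DataFrames; each
    frequency row sums to 1.
    """

    frequencies: pd.DataFrame
    counts: pd.DataFrame
    spots_per_condition: pd.Series

    def total_spots(self) -> int:
        return int(self.spots_per_condition.sum())


def dominant_type(p: ProportionTable) -> np.ndarray:
    """Per-spot label of the cell type with the largest proportion.

    Ties are broken by the lexicographically smallest type name.
    """
    order = np.argsort(np.asarray(p.cell_types, dtype=object))
    sorted_names = np.asarray(p.cell_types, dtype=object)[order]
    # argmax returns the first max, which after sorting is the smallest name
    idx = np.argmax(p.proportions[:, order], axis=1)
    return sorted_names[idx]


def enriched_spots(p: ProportionTable, cell_type: str, threshold: float = DEFAULT_ENRICHMENT_THRESHOLD) -> np.ndarray:
    """Barcodes of spots whose proportion of ``cell_type`` is >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    mask = p.column(cell_type) >= threshold
    return p.barcodes[mask]


def subset_frequencies(
    labels: Sequence[str],
    condition: Sequence[str],
    all_conditions: Optional[Sequence[str]] = None,
) -> CompositionSummary:
    """Per-condition frequency of each label plus raw counts.

    ``all_conditions`` may declare the expected condition set; any declared
    condition without spots raises.
    """
    labels = np.asarray(labels, dtype=object)
    condition = np.asarray(condition, dtype=object)
    if labels.shape != condition.shape:
        raise DataConsistencyError("labels and condition must have equal length")
    if labels.size == 0:
        raise DataConsistencyError("no spots provided")
    counts = pd.crosstab(pd.Series(condition, name="condition"), pd.Series(labels, name="label"))
    if all_conditions is not None:
        missing = [c for c in all_conditions if c not in counts.index or counts.loc[c].sum() == 0]
        if missing:
            raise DataConsistencyError(f"condition(s) with zero spots: {missing}")
        counts = counts.loc[list(all_conditions)]
    totals = counts.sum(axis=1)
    freqs = counts.div(totals, axis=0)
    return CompositionSummary(
        frequencies=freqs,
        counts=counts,
        spots_per_condition=totals.rename("n_spots"),
    )


@lru_cache(maxsize=32)
def _group_index_combinations(n: int, n1: int) -> np.ndarray:
    return np.array(list(combinations(range(n), n1)), dtype=np.intp)


def _exact_ranksum_p(v1: np.ndarray, v2: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Midranks handle ties; the p-value is the fraction of assignments whose
    rank sum is at least as far from its expectation as the observed one.
    """
    n1, n2 = len(v1), len(v2)
    pooled = np.concatenate([v1, v2])
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    combs = _group_index_combinations(n1 + n2, n1)
    w_all = ranks[combs].sum(axis=1)
    extreme = np.abs(w_all - mu) >= np.abs(w_obs - mu) - 1e-9
    return float(extreme.mean())


def marker_test(
    m: SpotMatrix,
    group: Sequence[bool],
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    group_name: str = "group1",
    up_only: bool = False,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum marker table between two spot groups.

    The p-value is exact (full enumeration over assignments) when both groups
    have at most 10 spots, otherwise the normal approximation with tie and
    continuity correction. The fold change is Seurat-style:
    ``log2((mean1 + 1) / (mean2 + 1))`` on de-logged normalized values.
    ``passes_lfc`` keeps ``|log2fc| > lfc_threshold`` (or only positive fold
    changes with ``up_only``). BH-adjusted p-values are always reported.
    """
    if m.normalized is None:
        raise DataConsistencyError("marker_test requires normalized values")
    group = np.asarray(group, dtype=bool)
    if group.shape != (m.n_spots,):
        raise DataConsistencyError("group mask length != number of spots")
    n1, n2 = int(group.sum()), int((~group).sum())
    if n1 == 0 or n2 == 0:
        raise DataConsistencyError("both groups must be non-empty")

    X = np.asarray(m.normalized.todense())
    delogged = np.expm1(X)
    exact = n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP
    records = []
    for gi in range(m.n_genes):
        v1 = X[gi, group]
        v2 = X[gi, ~group]
        mean1 = delogged[gi, group].mean()
        mean2 = delogged[gi, ~group].mean()
        if np.ptp(X[gi]) == 0:  # flat gene: no information
            p, lfc = 1.0, 0.0
        else:
            lfc = float(np.log2((mean1 + 1.0) / (mean2 + 1.0)))
            if exact:
                p = _exact_ranksum_p(v1, v2)
            else:
                p = float(
                    mannwhitneyu(
                        v1, v2, alternative="two-sided", method="asymptotic"
                    ).pvalue
                )
        records.append(
            {"gene": m.gene_ids[gi], "group": group_name, "log2fc": lfc, "p_value": p}
        )
    df = pd.DataFrame(records)
    df["p_adj"] = false_discovery_control(df["p_value"], method="bh")
    if up_only:
        df["passes_lfc"] = df["log2fc"] > lfc_threshold
    else:
        df["passes_lfc"] = df["log2fc"].abs() > lfc_threshold
    return df
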