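"""Synthetic Visium-like data with known ground truth.

Generates a hexagonal spot lattice, spatially patchy cell-type mixtures
(1-4 cells per spot, Dirichlet composition per spatial domain), negative
binomial counts with log-normal library-size variation, and planted gene
pairs whose spatial colocalization strength is a tunable effect size: each
planted pair shares a Gaussian-smoothed latent spatial field ``f`` (zero
mean, unit variance) that multiplies both genes' means by ``exp(gamma * f)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .composition import ProportionTable
from .errors import ConfigError
from .io import SpotMatrix, write_counts

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "make_hex_grid",
    "simulate_proportions",
    "simulate_counts",
    "simulate_dataset",
    "write_fixture",
    "read_truth",
    "default_config",
    "paired_gene_config",
]


@dataclass
class SimConfig:
    """All generator parameters for one synthetic dataset."""

    n_rows: int = 20
    n_cols: int = 20
    pitch: float = 1.0
    cell_types: Tuple[str, ...] = ("Cardiomyocyte", "Fibroblast", "Macrophage")
    gene_ids: Tuple[str, ...] = ()
    signature: Optional[np.ndarray] = None  # genes x types, mean expression
    domain_center: Optional[Tuple[float, float]] = None  # None = lattice centroid
    domain_radius: float = 0.0  # 0 disables the infiltrated disc
    dirichlet_alpha: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: {"background": (4.0, 2.0, 1.0), "infiltrated": (2.0, 2.0, 6.0)}
    )
    cells_per_spot: Tuple[int, int] = (1, 4)
    library_sigma: float = 0.35
    target_median_umi: float = 5000.0
    nb_dispersion: float = 2.0  # gamma shape; larger = closer to Poisson
    coloc_pairs: Tuple[Tuple[str, str, float], ...] = ()
    field_smoothness: float = 1.5  # Gaussian kernel bandwidth (coordinate units)
    condition: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.signature is not None:
            self.signature = np.asarray(self.signature, dtype=float)
        self.validate()

    def validate(self) -> None:
        problems = []
        if self.n_rows < 1 or self.n_cols < 1:
            problems.append(f"lattice dims must be >=1, got {self.n_rows}x{self.n_cols}")
        if self.pitch <= 0:
            problems.append(f"pitch must be positive, got {self.pitch}")
        lo, hi = self.cells_per_spot
        if lo < 1 or hi < lo:
            problems.append(f"cells_per_spot bounds invalid: ({lo}, {hi})")
        for name, alpha in self.dirichlet_alpha.items():
            if len(alpha) != len(self.cell_types):
                problems.append(
                    f"dirichlet_alpha[{name}] has {len(alpha)} entries for "
                    f"{len(self.cell_types)} cell types"
                )
            if any(a <= 0 for a in alpha):
                problems.append(f"dirichlet_alpha[{name}] must be > 0")
        if "background" not in self.dirichlet_alpha:
            problems.append("dirichlet_alpha must define 'background'")
        if self.domain_radius > 0 and "infiltrated" not in self.dirichlet_alpha:
            problems.append("domain_radius > 0 requires dirichlet_alpha['infiltrated']")
        if self.signature is not None:
            if self.signature.shape != (len(self.gene_ids), len(self.cell_types)):
                problems.append(
                    f"signature shape {self.signature.shape} != "
                    f"({len(self.gene_ids)}, {len(self.cell_types)})"
                )
            elif np.any(self.signature < 0):
                problems.append("signature means must be >= 0")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            problems.append("gene_ids must be unique")
        if self.nb_dispersion <= 0:
            problems.append(f"nb_dispersion must be positive, got {self.nb_dispersion}")
        if self.field_smoothness <= 0:
            problems.append("field_smoothness must be positive")
        if self.library_sigma < 0:
            problems.append("library_sigma must be >= 0")
        known = set(self.gene_ids)
        for a, b, gamma in self.coloc_pairs:
            if gamma < 0:
                problems.append(f"coloc pair ({a}, {b}) has negative gamma {gamma}")
            if known and (a not in known or b not in known):
                problems.append(f"coloc pair ({a}, {b}) references unknown gene(s)")
        if problems:
            raise ConfigError(problems)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.signature is not None:
            d["signature"] = self.signature.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("signature") is not None:
            d["signature"] = np.asarray(d["signature"], dtype=float)
        for key in ("cell_types", "gene_ids", "cells_per_spot"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("domain_center") is not None:
            d["domain_center"] = tuple(d["domain_center"])
        if "coloc_pairs" in d:
            d["coloc_pairs"] = tuple((a, b, float(g)) for a, b, g in d["coloc_pairs"])
        if "dirichlet_alpha" in d:
            d["dirichlet_alpha"] = {k: tuple(v) for k, v in d["dirichlet_alpha"].items()}
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted parameters of one simulated dataset."""

    seed: int
    config: SimConfig
    domains: Optional[np.ndarray] = None  # per-spot domain label
    proportions: Optional[ProportionTable] = None
    coloc_pairs: Tuple[Tuple[str, str, float], ...] = ()
    fields: Dict[str, np.ndarray] = field(default_factory=dict)  # "a|b" -> field
    array_row: Optional[np.ndarray] = None
    array_col: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "domains": None if self.domains is None else list(self.domains),
            "proportions": None
            if self.proportions is None
            else {
                "barcodes": list(self.proportions.barcodes),
                "cell_types": list(self.proportions.cell_types),
                "proportions": self.proportions.proportions.tolist(),
            },
            "coloc_pairs": [list(p) for p in self.coloc_pairs],
            "fields": {k: v.tolist() for k, v in self.fields.items()},
            "array_row": None if self.array_row is None else self.array_row.tolist(),
            "array_col": None if self.array_col is None else self.array_col.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        props = d.get("proportions")
        return cls(
            seed=d["seed"],
            config=SimConfig.from_dict(d["config"]),
            domains=None if d.get("domains") is None else np.asarray(d["domains"], dtype=object),
            proportions=None
            if props is None
            else ProportionTable(
                barcodes=np.asarray(props["barcodes"], dtype=object),
                cell_types=props["cell_types"],
                proportions=np.asarray(props["proportions"], dtype=float),
            ),
            coloc_pairs=tuple((a, b, float(g)) for a, b, g in d.get("coloc_pairs", [])),
            fields={k: np.asarray(v, dtype=float) for k, v in d.get("fields", {}).items()},
            array_row=None if d.get("array_row") is None else np.asarray(d["array_row"], dtype=int),
            array_col=None if d.get("array_col") is None else np.asarray(d["array_col"], dtype=int),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return json.dumps(self.to_dict(), sort_keys=True) == json.dumps(
            other.to_dict(), sort_keys=True
        )


def make_hex_grid(n_rows: int, n_cols: int, pitch: float = 1.0) -> np.ndarray:
    """Triangular-lattice coordinates: odd rows offset by pitch/2, row
    spacing pitch * sqrt(3)/2. Row-major order."""
    if n_rows < 1 or n_cols < 1:
        raise ConfigError(f"lattice dims must be >=1, got {n_rows}x{n_cols}")
    if pitch <= 0:
        raise ConfigError(f"pitch must be positive, got {pitch}")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows = rows.ravel()
    cols = cols.ravel()
    x = cols * pitch + (rows % 2) * pitch / 2.0
    y = rows * pitch * np.sqrt(3.0) / 2.0
    return np.column_stack([x, y])


def _grid_indices(n_rows: int, n_cols: int) -> Tuple[np.ndarray, np.ndarray]:
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    return rows.ravel(), cols.ravel()


def _spot_barcodes(n: int) -> np.ndarray:
    return np.array([f"spot-{i:05d}" for i in range(n)], dtype=object)


def _domain_labels(coords: np.ndarray, cfg: SimConfig) -> np.ndarray:
    labels = np.full(len(coords), "background", dtype=object)
    if cfg.domain_radius > 0:
        center = cfg.domain_center
        if center is None:
            center = coords.mean(axis=0)
        dist = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
        labels[dist <= cfg.domain_radius] = "infiltrated"
    return labels


def simulate_proportions(
    coords: np.ndarray, cfg: SimConfig, seed: Optional[int] = None
) -> Tuple[ProportionTable, SyntheticTruth]:
    """Draw per-spot cell-type proportions.

    Each spot draws a cell count uniform over ``cells_per_spot``, a Dirichlet
    composition with its domain's alpha, then discretizes the composition
    over that many cells (multinomial), so proportions are multiples of
    1/n_cells — a small mixture of whole cells, not a continuous fraction.
    """
    if seed is None:
        seed = cfg.seed
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    domains = _domain_labels(coords, cfg)
    lo, hi = cfg.cells_per_spot
    n_cells = rng.integers(lo, hi + 1, size=n)
    t = len(cfg.cell_types)
    props = np.empty((n, t))
    for s in range(n):
        alpha = np.asarray(cfg.dirichlet_alpha[domains[s]], dtype=float)
        probs = rng.dirichlet(alpha)
        cells = rng.multinomial(n_cells[s], probs)
        props[s] = cells / n_cells[s]
    table = ProportionTable(
        barcodes=_spot_barcodes(n), cell_types=list(cfg.cell_types), proportions=props
    )
    truth = SyntheticTruth(seed=seed, config=cfg, domains=domains, proportions=table)
    return table, truth


def _smooth_field(
    coords: np.ndarray, bandwidth: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized Gaussian-kernel-smoothed white noise over the spots."""
    z = rng.standard_normal(len(coords))
    d2 = cdist(coords, coords, "sqeuclidean")
    w = np.exp(-d2 / (2.0 * bandwidth**2))
    f = (w @ z) / w.sum(axis=1)
    sd = f.std()
    if sd == 0:  # single spot
        return np.zeros_like(f)
    return (f - f.mean()) / sd


def simulate_counts(
    coords: np.ndarray,
    props: ProportionTable,
    cfg: SimConfig,
    seed: Optional[int] = None,
) -> Tuple[SpotMatrix, SyntheticTruth]:
    """Draw NB counts given proportions, planting colocalized pairs.

    Per-spot gene means are ``library factor x sum_t proportion[t] x
    signature[gene, t]``, globally scaled so the median expected spot total
    equals ``target_median_umi``; planted pairs multiply both genes' means by
    ``exp(gamma * f)`` with a shared smooth field ``f``. Counts are
    gamma-Poisson with shape ``nb_dispersion``.
    """
    if seed is None:
        seed = cfg.seed
    if cfg.signature is None or not cfg.gene_ids:
        raise ConfigError("simulate_counts requires gene_ids and a signature matrix")
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if props.n_spots != n:
        raise ConfigError("proportion table size != number of coordinates")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))

    mean = cfg.signature @ props.proportions.T  # genes x spots
    totals = mean.sum(axis=0)
    scale = cfg.target_median_umi / np.median(totals[totals > 0])
    mean = mean * scale

    gene_pos = {g: i for i, g in enumerate(cfg.gene_ids)}
    fields: Dict[str, np.ndarray] = {}
    for a, b, gamma in cfg.coloc_pairs:
        f = _smooth_field(coords, cfg.field_smoothness, rng)
        if gamma > 0:
            fields[f"{a}|{b}"] = f
            boost = np.exp(gamma * f)
            mean[gene_pos[a]] *= boost
            mean[gene_pos[b]] *= boost

    lib = np.exp(rng.normal(0.0, cfg.library_sigma, size=n))
    mean = mean * lib[None, :]

    theta = cfg.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam)

    m = SpotMatrix(
        counts=sp.csr_matrix(counts.astype(np.int64)),
        gene_ids=np.asarray(cfg.gene_ids, dtype=object),
        gene_names=np.asarray(cfg.gene_ids, dtype=object),
        barcodes=props.barcodes.copy(),
        coords=coords,
        condition=cfg.condition,
    )
    ar, ac = _grid_indices(cfg.n_rows, cfg.n_cols) if n == cfg.n_rows * cfg.n_cols else (None, None)
    truth = SyntheticTruth(
        seed=seed,
        config=cfg,
        proportions=props,
        coloc_pairs=cfg.coloc_pairs,
        fields=fields,
        array_row=ar,
        array_col=ac,
    )
    return m, truth


def simulate_dataset(cfg: SimConfig, seed: Optional[int] = None):
    """Full generator: grid -> proportions -> counts.

    Returns ``(SpotMatrix, ProportionTable, SyntheticTruth)`` with a single
    merged truth record.
    """
    if seed is None:
        seed = cfg.seed
    coords = make_hex_grid(cfg.n_rows, cfg.n_cols, cfg.pitch)
    props, ptruth = simulate_proportions(coords, cfg, seed)
    m, ctruth = simulate_counts(coords, props, cfg, seed)
    ar, ac = _grid_indices(cfg.n_rows, cfg.n_cols)
    truth = SyntheticTruth(
        seed=seed,
        config=cfg,
        domains=ptruth.domains,
        proportions=props,
        coloc_pairs=ctruth.coloc_pairs,
        fields=ctruth.fields,
        array_row=ar,
        array_col=ac,
    )
    return m, props, truth


def write_fixture(m: SpotMatrix, props: ProportionTable, truth: SyntheticTruth, out_dir) -> dict:
    """Write a full round-trippable plain-text fixture.

    Emits matrix.mtx, features.tsv, barcodes.tsv, positions.csv (headered
    SpaceRanger dialect, coordinates as full-resolution pixels),
    proportions.csv and truth.json. Byte-stable for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_counts(m, out_dir)

    if truth.array_row is not None:
        ar, ac = truth.array_row, truth.array_col
    else:
        ar = np.zeros(m.n_spots, dtype=int)
        ac = np.arange(m.n_spots)
    pos = pd.DataFrame(
        {
            "barcode": m.barcodes,
            "in_tissue": np.ones(m.n_spots, dtype=int),
            "array_row": ar,
            "array_col": ac,
            "pxl_row_in_fullres": m.coords[:, 1],
            "pxl_col_in_fullres": m.coords[:, 0],
        }
    )
    paths["positions"] = out_dir / "positions.csv"
    pos.to_csv(paths["positions"], index=False)

    paths["proportions"] = out_dir / "proportions.csv"
    props.to_frame().to_csv(paths["proportions"], index=False)

    paths["truth"] = out_dir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, sort_keys=True, indent=None, separators=(",", ":"))
    return paths


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))


def default_config(**overrides) -> SimConfig:
    """A realistic small config: 3 cell types with marker gene blocks and an
    immune-infiltrated disc in the lattice center."""
    cell_types = ("Cardiomyocyte", "Fibroblast", "Macrophage")
    genes = []
    rows = []
    for t, ctype in enumerate(cell_types):
        for k in range(6):  # 6 markers per type, 8x enriched
            genes.append(f"{ctype[:3].upper()}{k}")
            row = np.ones(len(cell_types))
            row[t] = 8.0
            rows.append(row)
    for k in range(6):  # housekeeping genes, flat across types
        genes.append(f"HK{k}")
        rows.append(np.full(len(cell_types), 2.0))
    cfg = dict(
        cell_types=cell_types,
        gene_ids=tuple(genes),
        signature=np.array(rows),
        domain_radius=5.0,
        dirichlet_alpha={
            "background": (4.0, 2.0, 1.0),
            "infiltrated": (2.0, 2.0, 6.0),
        },
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def paired_gene_config(
    gammas: Sequence[float],
    n_extra_genes: int = 60,
    **overrides,
) -> SimConfig:
    """Config tailored to colocalization calibration/power studies.

    All genes are flat across cell types (so spatial structure comes only
    from planted fields), and one gene pair is planted per requested gamma;
    gamma = 0 entries act as matched null pairs. The background gene block is
    deliberately large so planted genes are a small fraction of each spot's
    library and median-scaling normalization does not leak the planted
    spatial fields into unrelated genes.
    """
    genes: List[str] = []
    pairs = []
    for k, g in enumerate(gammas):
        a, b = f"PAIRA{k}", f"PAIRB{k}"
        genes += [a, b]
        pairs.append((a, b, float(g)))
    genes += [f"BG{k}" for k in range(n_extra_genes)]
    n_types = 3
    cfg = dict(
        cell_types=("T1", "T2", "T3"),
        gene_ids=tuple(genes),
        signature=np.full((len(genes), n_types), 4.0),
        dirichlet_alpha={"background": (1.0, 1.0, 1.0)},
        domain_radius=0.0,
        coloc_pairs=tuple(pairs),
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
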