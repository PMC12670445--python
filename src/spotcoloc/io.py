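"""Readers/writers for spot-level expression data and the QC/normalization steps.

Supports the SpaceRanger-style trio (MatrixMarket counts + features/barcodes
TSV), both tissue-position CSV dialects (headered and legacy headerless), and
a deconvolution proportion CSV. Gzip is auto-detected by magic bytes, never by
file extension.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import DataConsistencyError, FormatError

__all__ = [
    "SpotMatrix",
    "PositionTable",
    "QCReport",
    "read_counts",
    "read_positions",
    "attach_positions",
    "qc_filter",
    "normalize",
    "read_proportions",
    "write_counts",
]

#: Spacing conventions for converting array (row, col) indices to Cartesian
#: coordinates on the interleaved Visium lattice: columns advance by half a
#: pitch because odd/even rows interleave, rows advance by sqrt(3)/2.
HEX_COL_STEP = 0.5
HEX_ROW_STEP = np.sqrt(3.0) / 2.0

GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path):
    """Open plain or gzip text transparently, sniffing the magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_binary(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rb")
    return open(path, "rb")


@dataclass
class SpotMatrix:
    """Gene-by-spot count matrix with identifiers, coordinates and condition.

    ``counts`` is a CSR sparse matrix of non-negative integers with one row
    per gene and one column per spot. ``normalized`` (same shape, float) is
    populated by :func:`normalize` or can be supplied from an external tool.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray
    coords: Optional[np.ndarray] = None
    condition: Optional[str] = None
    normalized: Optional[sp.csr_matrix] = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_names) != n_genes:
            raise DataConsistencyError(
                f"counts has {n_genes} genes but {len(self.gene_ids)} ids / "
                f"{len(self.gene_names)} names"
            )
        if len(self.barcodes) != n_spots:
            raise DataConsistencyError(
                f"counts has {n_spots} spots but {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != n_spots:
            raise DataConsistencyError("barcodes are not unique")
        if len(set(self.gene_ids)) != n_genes:
            raise DataConsistencyError("gene_ids are not unique")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise DataConsistencyError("counts contain negative values")
            if not np.allclose(data, np.round(data)):
                raise DataConsistencyError("counts contain non-integer values")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n_spots, 2):
                raise DataConsistencyError(
                    f"coords shape {self.coords.shape} != ({n_spots}, 2)"
                )
            uniq = np.unique(self.coords, axis=0)
            if len(uniq) != n_spots:
                raise DataConsistencyError("two spots share identical coordinates")
        if self.normalized is not None:
            self.normalized = sp.csr_matrix(self.normalized)
            if self.normalized.shape != self.counts.shape:
                raise DataConsistencyError("normalized shape differs from counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def spot_totals(self) -> np.ndarray:
        """Total UMI count per spot."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per spot."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise KeyError(f"gene {gene_id!r} not found")
        return int(idx[0])

    def expression(self, gene_id: str, source: str = "normalized") -> np.ndarray:
        """Dense per-spot expression vector for one gene.

        ``source`` is ``"normalized"`` (requires :func:`normalize` first) or
        ``"raw"`` (integer counts).
        """
        i = self.gene_index(gene_id)
        if source == "raw":
            return np.asarray(self.counts[i].todense()).ravel().astype(float)
        if source == "normalized":
            if self.normalized is None:
                raise DataConsistencyError(
                    "normalized values requested but matrix is not normalized"
                )
            return np.asarray(self.normalized[i].todense()).ravel()
        raise ValueError(f"unknown expression source {source!r}")

    def subset_spots(self, mask: np.ndarray) -> "SpotMatrix":
        """New SpotMatrix keeping the spots selected by boolean/index mask."""
        mask = np.asarray(mask)
        return SpotMatrix(
            counts=self.counts[:, mask].tocsr(),
            gene_ids=self.gene_ids,
            gene_names=self.gene_names,
            barcodes=self.barcodes[mask],
            coords=None if self.coords is None else self.coords[mask],
            condition=self.condition,
            normalized=None if self.normalized is None else self.normalized[:, mask].tocsr(),
        )


@dataclass
class PositionTable:
    """Tissue-position table in the SpaceRanger dialect."""

    barcode: np.ndarray
    in_tissue: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    pixel_x: np.ndarray
    pixel_y: np.ndarray

    def __post_init__(self):
        self.barcode = np.asarray(self.barcode, dtype=object)
        self.in_tissue = np.asarray(self.in_tissue, dtype=int)
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        self.pixel_x = np.asarray(self.pixel_x, dtype=float)
        self.pixel_y = np.asarray(self.pixel_y, dtype=float)
        if len(set(self.barcode)) != len(self.barcode):
            raise DataConsistencyError("position table barcodes are not unique")
        if not np.isin(self.in_tissue, (0, 1)).all():
            raise DataConsistencyError("in_tissue values must be 0 or 1")

    def __len__(self) -> int:
        return len(self.barcode)


@dataclass
class QCReport:
    """Spot counts before/after a QC filter."""

    n_input: int
    n_kept: int
    n_removed: int
    min_umi: int
    min_genes: int


def read_counts(matrix_path, features_path, barcodes_path, condition=None) -> SpotMatrix:
    """Read a filtered feature-barcode trio into a :class:`SpotMatrix`.

    The MatrixMarket file must be in coordinate format with genes as rows and
    spots as columns; features/barcodes are TSV, plain or gzipped.
    """
    with _open_binary(matrix_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # malformed header or body
            raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and (np.any(mat.data < 0) or not np.allclose(mat.data, np.round(mat.data))):
        raise FormatError(f"{matrix_path} contains negative or non-integer counts")

    with _open_text(features_path) as fh:
        feats = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    with _open_text(barcodes_path) as fh:
        bcs = pd.read_csv(fh, sep="\t", header=None, dtype=str)

    if len(feats) != mat.shape[0]:
        raise DataConsistencyError(
            f"matrix declares {mat.shape[0]} genes but features file has {len(feats)} rows"
        )
    if len(bcs) != mat.shape[1]:
        raise DataConsistencyError(
            f"matrix declares {mat.shape[1]} spots but barcodes file has {len(bcs)} rows"
        )
    gene_ids = feats.iloc[:, 0].to_numpy(dtype=object)
    gene_names = (feats.iloc[:, 1] if feats.shape[1] > 1 else feats.iloc[:, 0]).to_numpy(dtype=object)
    counts = sp.csr_matrix(mat.astype(np.int64))
    counts.eliminate_zeros()
    return SpotMatrix(
        counts=counts,
        gene_ids=gene_ids,
        gene_names=gene_names,
        barcodes=bcs.iloc[:, 0].to_numpy(dtype=object),
        condition=condition,
    )


_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def read_positions(positions_path) -> PositionTable:
    """Read a tissue-positions CSV, auto-detecting headered vs headerless."""
    with _open_text(positions_path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.split(",")[0].strip().lower()
    with _open_text(positions_path) as fh:
        df = pd.read_csv(fh, header=0 if has_header else None)
    if df.shape[1] < 6:
        raise FormatError(
            f"{positions_path}: expected >=6 columns, found {df.shape[1]}"
        )
    df = df.iloc[:, :6]
    df.columns = _POSITION_COLUMNS
    in_tissue = df["in_tissue"].to_numpy()
    if not np.isin(in_tissue, (0, 1)).all():
        bad = sorted(set(in_tissue) - {0, 1})
        raise FormatError(f"{positions_path}: non-binary in_tissue values {bad}")
    return PositionTable(
        barcode=df["barcode"].astype(str).to_numpy(dtype=object),
        in_tissue=in_tissue,
        array_row=df["array_row"].to_numpy(),
        array_col=df["array_col"].to_numpy(),
        # SpaceRanger stores pixel row before pixel column
        pixel_x=df["pxl_col_in_fullres"].to_numpy(dtype=float),
        pixel_y=df["pxl_row_in_fullres"].to_numpy(dtype=float),
    )


def attach_positions(m: SpotMatrix, p: PositionTable, use_pixels: bool = True) -> SpotMatrix:
    """Attach per-spot coordinates and drop spots outside the tissue.

    With ``use_pixels`` the full-resolution pixel coordinates are used
    verbatim; otherwise array indices are mapped onto the interleaved lattice
    (x = col * 0.5, y = row * sqrt(3)/2) so inter-spot distances are uniform.
    """
    lookup = {bc: i for i, bc in enumerate(p.barcode)}
    missing = [bc for bc in m.barcodes if bc not in lookup]
    if missing:
        raise DataConsistencyError(
            f"{len(missing)} matrix barcodes absent from position table "
            f"(first: {missing[0]!r})"
        )
    rows = np.array([lookup[bc] for bc in m.barcodes])
    keep = p.in_tissue[rows] == 1
    rows = rows[keep]
    if use_pixels:
        coords = np.column_stack([p.pixel_x[rows], p.pixel_y[rows]])
    else:
        coords = np.column_stack(
            [p.array_col[rows] * HEX_COL_STEP, p.array_row[rows] * HEX_ROW_STEP]
        )
    if len(coords) and len(np.unique(coords, axis=0)) != len(coords):
        raise DataConsistencyError("duplicate coordinates after position attachment")
    out = m.subset_spots(np.flatnonzero(keep))
    return replace(out, coords=coords)


def qc_filter(m: SpotMatrix, min_umi: int = 500, min_genes: int = 300):
    """Keep spots with strictly more than ``min_umi`` UMIs and ``min_genes``
    detected genes; returns ``(filtered, QCReport)``.

    The inequalities are strict: a spot at exactly the threshold is removed.
    """
    totals = m.spot_totals()
    detected = m.genes_detected()
    keep = (totals > min_umi) & (detected > min_genes)
    filtered = m.subset_spots(keep)
    report = QCReport(
        n_input=m.n_spots,
        n_kept=filtered.n_spots,
        n_removed=int(m.n_spots - filtered.n_spots),
        min_umi=min_umi,
        min_genes=min_genes,
    )
    return filtered, report


def normalize(m: SpotMatrix) -> SpotMatrix:
    """Median-library-size scaling followed by log1p.

    Each spot's counts are scaled so its total equals the median spot total,
    then log(1 + x) is applied. This is a deliberately simple stand-in for
    variance-stabilizing transforms; externally normalized matrices can be
    attached directly to :attr:`SpotMatrix.normalized` instead.
    """
    if m.n_spots == 0:
        raise DataConsistencyError("cannot normalize a matrix with zero spots")
    totals = m.spot_totals().astype(float)
    if np.any(totals == 0):
        raise DataConsistencyError("cannot normalize: spot(s) with zero total counts")
    target = float(np.median(totals))
    scaled = (m.counts.astype(float) @ sp.diags(target / totals)).tocsr()
    scaled.data = np.log1p(scaled.data)
    return replace(m, normalized=scaled)


def read_proportions(path):
    """Read a deconvolution proportion CSV (barcode + one column per type).

    Rows are renormalized to sum exactly to 1 when their sum is within 1e-3
    of 1; larger deviations or negative values raise.
    """
    from .composition import ProportionTable

    with _open_text(path) as fh:
        df = pd.read_csv(fh)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected barcode column plus >=1 cell type")
    barcodes = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    types = [str(c) for c in df.columns[1:]]
    props = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(props < 0):
        raise DataConsistencyError(f"{path}: negative proportion values")
    sums = props.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-3
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise DataConsistencyError(
            f"{path}: row {i} ({barcodes[i]}) sums to {sums[i]:.6g}, not 1"
        )
    props = props / sums[:, None]
    return ProportionTable(barcodes=barcodes, cell_types=types, proportions=props)


def write_counts(m: SpotMatrix, out_dir) -> dict:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` (plain text).

    Returns the paths written. Round-trips through :func:`read_counts`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    coo = m.counts.tocoo()
    coo.eliminate_zeros()
    scipy.io.mmwrite(str(paths["matrix"]), coo, field="integer")
    feats = pd.DataFrame(
        {
            0: m.gene_ids,
            1: m.gene_names,
            2: ["Gene Expression"] * m.n_genes,
        }
    )
    feats.to_csv(paths["features"], sep="\t", header=False, index=False)
    pd.Series(m.barcodes).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    return paths
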