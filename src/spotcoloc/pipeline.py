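"""End-to-end orchestration: read -> QC -> normalize -> graph -> coloc +
composition, one condition (slide) at a time.

Conditions are processed as independent datasets with independently built
graphs and are compared only at the summary level; spots are never pooled
across slides. A run is fully determined by (inputs, config, seed): rerunning
with the same config writes byte-identical outputs (wall time is reported to
the log only, never serialized).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import ColocMatrix, coloc_matrix
from .composition import (
    CompositionSummary,
    dominant_type,
    enriched_spots,
    marker_test,
    subset_frequencies,
)
from .errors import ConfigError, SpotColocError
from .graph import build_delaunay_graph, degree_summary, write_edges
from .io import (
    attach_positions,
    normalize,
    qc_filter,
    read_counts,
    read_positions,
    read_proportions,
)

__all__ = ["ConditionInput", "RunConfig", "RunReport", "RunResult", "validate_config", "run"]

logger = logging.getLogger(__name__)


@dataclass
class ConditionInput:
    name: str
    matrix: Path
    features: Path
    barcodes: Path
    positions: Path
    proportions: Optional[Path] = None


@dataclass
class RunConfig:
    conditions: List[ConditionInput]
    out_dir: Path
    row_genes: Optional[Path] = None
    col_genes: Optional[Path] = None
    min_umi: int = 500
    min_genes: int = 300
    n_perm: int = 100
    alpha: float = 0.05
    seed: int = 0
    expression_source: str = "normalized"
    use_pixels: bool = True
    enrichment_threshold: float = 0.25
    enriched_type: Optional[str] = None
    marker_type: Optional[str] = None


@dataclass
class RunReport:
    version: str
    seed: int
    config_echo: dict
    conditions: Dict[str, dict] = field(default_factory=dict)
    wall_time_s: Optional[float] = None  # logged, never serialized

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config_echo,
            "conditions": self.conditions,
        }


@dataclass
class RunResult:
    coloc: Dict[str, ColocMatrix]
    composition: Optional[CompositionSummary]
    markers: Optional[pd.DataFrame]
    report: RunReport


_CONDITION_PATH_KEYS = ("matrix", "features", "barcodes", "positions")


def validate_config(path) -> RunConfig:
    """Parse + validate a YAML/JSON run config, reporting all problems at once."""
    path = Path(path)
    problems: List[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError([f"cannot parse config: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    base = path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    conditions = []
    for i, cond in enumerate(raw.get("conditions", []) or []):
        name = cond.get("name", f"condition{i}")
        kwargs = {"name": name}
        for key in _CONDITION_PATH_KEYS:
            if key not in cond:
                problems.append(f"condition {name!r}: missing {key!r}")
                continue
            p = _resolve(cond[key])
            if not p.exists():
                problems.append(f"condition {name!r}: {key} path does not exist: {p}")
            kwargs[key] = p
        if cond.get("proportions") is not None:
            p = _resolve(cond["proportions"])
            if not p.exists():
                problems.append(f"condition {name!r}: proportions path does not exist: {p}")
            kwargs["proportions"] = p
        if len([k for k in kwargs if k != "name"]) == len(_CONDITION_PATH_KEYS) + (
            1 if "proportions" in kwargs else 0
        ):
            conditions.append(ConditionInput(**kwargs))
    if not raw.get("conditions"):
        problems.append("config must declare at least one condition")

    gene_lists = {}
    for key in ("row_genes", "col_genes"):
        if raw.get(key) is not None:
            p = _resolve(raw[key])
            if not p.exists():
                problems.append(f"{key} path does not exist: {p}")
            gene_lists[key] = p

    n_perm = int(raw.get("n_perm", 100))
    if n_perm < 1:
        problems.append(f"n_perm must be >= 1, got {n_perm}")
    alpha = float(raw.get("alpha", 0.05))
    if not 0 < alpha <= 1:
        problems.append(f"alpha must be in (0, 1], got {alpha}")
    source = raw.get("expression_source", "normalized")
    if source not in ("normalized", "raw"):
        problems.append(f"expression_source must be 'normalized' or 'raw', got {source!r}")
    thr = float(raw.get("enrichment_threshold", 0.25))
    if not 0 <= thr <= 1:
        problems.append(f"enrichment_threshold must be in [0, 1], got {thr}")
    if "out_dir" not in raw:
        problems.append("config must declare out_dir")

    if problems:
        raise ConfigError(problems)

    return RunConfig(
        conditions=conditions,
        out_dir=_resolve(raw["out_dir"]),
        row_genes=gene_lists.get("row_genes"),
        col_genes=gene_lists.get("col_genes"),
        min_umi=int(raw.get("min_umi", 500)),
        min_genes=int(raw.get("min_genes", 300)),
        n_perm=n_perm,
        alpha=alpha,
        seed=int(raw.get("seed", 0)),
        expression_source=source,
        use_pixels=bool(raw.get("use_pixels", True)),
        enrichment_threshold=thr,
        enriched_type=raw.get("enriched_type"),
        marker_type=raw.get("marker_type"),
    )


def _read_gene_list(path: Optional[Path]) -> List[str]:
    if path is None:
        return []
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def _stage(name: str):
    """Context wrapper attaching the stage name to any pipeline error."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise SpotColocError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline and write all outputs under ``cfg.out_dir``."""
    t0 = time.monotonic()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    row_genes = _read_gene_list(cfg.row_genes)
    col_genes = _read_gene_list(cfg.col_genes)

    report = RunReport(
        version=__version__,
        seed=cfg.seed,
        config_echo={
            "min_umi": cfg.min_umi,
            "min_genes": cfg.min_genes,
            "n_perm": cfg.n_perm,
            "alpha": cfg.alpha,
            "expression_source": cfg.expression_source,
            "enrichment_threshold": cfg.enrichment_threshold,
            "enriched_type": cfg.enriched_type,
            "marker_type": cfg.marker_type,
            "conditions": [c.name for c in cfg.conditions],
            "row_genes": row_genes,
            "col_genes": col_genes,
        },
    )

    coloc_results: Dict[str, ColocMatrix] = {}
    labels_frames = []
    marker_frames = []

    for cond in cfg.conditions:
        cdir = out_dir / cond.name
        cdir.mkdir(exist_ok=True)
        stats: dict = {}

        with _stage(f"{cond.name}/read"):
            m = read_counts(cond.matrix, cond.features, cond.barcodes, condition=cond.name)
            stats["loaded_spots"] = m.n_spots
            stats["genes"] = m.n_genes
            pos = read_positions(cond.positions)
            m = attach_positions(m, pos, use_pixels=cfg.use_pixels)
            stats["in_tissue_spots"] = m.n_spots

        with _stage(f"{cond.name}/qc"):
            m, qc = qc_filter(m, min_umi=cfg.min_umi, min_genes=cfg.min_genes)
            stats["post_qc_spots"] = qc.n_kept
            stats["qc_removed_spots"] = qc.n_removed
            logger.info("%s: %d spots pass QC (%d removed)", cond.name, qc.n_kept, qc.n_removed)

        with _stage(f"{cond.name}/normalize"):
            m = normalize(m)

        with _stage(f"{cond.name}/graph"):
            g = build_delaunay_graph(m.coords)
            deg, hist = degree_summary(g)
            stats["graph_edges"] = g.n_edges
            stats["degree_histogram"] = hist
            write_edges(g, m.barcodes, cdir / "edges.tsv")

        if row_genes and col_genes:
            with _stage(f"{cond.name}/coloc"):
                cm = coloc_matrix(
                    m,
                    row_genes,
                    col_genes,
                    g,
                    n_perm=cfg.n_perm,
                    alpha=cfg.alpha,
                    seed=cfg.seed,
                    source=cfg.expression_source,
                )
                coloc_results[cond.name] = cm
                cm.to_long_frame().to_csv(cdir / "coloc_long.tsv", sep="\t", index=False)
                pd.DataFrame(cm.scores, index=cm.row_genes, columns=cm.col_genes).to_csv(
                    cdir / "coloc_scores.csv"
                )
                pd.DataFrame(cm.p_values, index=cm.row_genes, columns=cm.col_genes).to_csv(
                    cdir / "coloc_pvalues.csv"
                )
        else:
            # degenerate run: still emit empty tables for downstream tooling
            pd.DataFrame(
                columns=["gene_a", "gene_b", "score", "p_value", "p_adj", "n_perm", "seed"]
            ).to_csv(cdir / "coloc_long.tsv", sep="\t", index=False)

        if cond.proportions is not None:
            with _stage(f"{cond.name}/composition"):
                props = read_proportions(cond.proportions)
                keep = pd.Index(props.barcodes).isin(m.barcodes)
                props = type(props)(
                    barcodes=props.barcodes[keep],
                    cell_types=props.cell_types,
                    proportions=props.proportions[keep],
                )
                dom = dominant_type(props)
                lab = pd.DataFrame(
                    {"barcode": props.barcodes, "label": dom, "condition": cond.name}
                )
                lab.to_csv(cdir / "dominant.tsv", sep="\t", index=False)
                labels_frames.append(lab)
                stats["dominant_counts"] = (
                    pd.Series(dom).value_counts().sort_index().astype(int).to_dict()
                )
                if cfg.enriched_type is not None:
                    enr = enriched_spots(props, cfg.enriched_type, cfg.enrichment_threshold)
                    stats["enriched_spots"] = int(len(enr))

                if cfg.marker_type is not None:
                    bc_to_col = {bc: i for i, bc in enumerate(m.barcodes)}
                    cols = np.array([bc_to_col[bc] for bc in props.barcodes])
                    sub = m.subset_spots(cols)
                    mask = dom == cfg.marker_type
                    if mask.any() and (~mask).any():
                        mt = marker_test(sub, mask, group_name=cfg.marker_type)
                        mt.insert(0, "condition", cond.name)
                        marker_frames.append(mt)
                    else:
                        logger.warning(
                            "%s: marker group %r empty or exhaustive; skipping markers",
                            cond.name,
                            cfg.marker_type,
                        )

        report.conditions[cond.name] = stats

    composition = None
    if labels_frames:
        lab_all = pd.concat(labels_frames, ignore_index=True)
        composition = subset_frequencies(lab_all["label"], lab_all["condition"])
        composition.frequencies.to_csv(out_dir / "frequencies.tsv", sep="\t")
        composition.counts.to_csv(out_dir / "label_counts.tsv", sep="\t")

    markers = None
    if marker_frames:
        markers = pd.concat(marker_frames, ignore_index=True)
        markers.to_csv(out_dir / "markers.tsv", sep="\t", index=False)

    report.wall_time_s = time.monotonic() - t0
    logger.info("run finished in %.2f s", report.wall_time_s)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, sort_keys=True, indent=2)
        fh.write("\n")

    return RunResult(coloc=coloc_results, composition=composition, markers=markers, report=report)
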