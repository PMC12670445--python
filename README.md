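# spotcoloc

Spot-level spatial transcriptomics analysis toolkit:

- **I/O + QC** (`spotcoloc.io`) — read SpaceRanger-style feature-barcode
  trios (MatrixMarket + TSV, gzip auto-detected by magic bytes) and
  tissue-position CSVs (headered or legacy headerless), attach coordinates,
  filter spots with strictly more than 500 UMIs and 300 detected genes, and
  apply median-library-size + log1p normalization (externally normalized
  matrices can be plugged in instead).
- **Spatial graph** (`spotcoloc.graph`) — parameter-free undirected neighbor
  graph from Delaunay triangulation of the 2D spot coordinates, with
  neighborhood averaging (focal spot excluded by default) and edge-list TSV
  export/import. A deterministic micro-jitter (1e-9 of the bounding-box
  diagonal) makes near-degenerate configurations reproducible.
- **Colocalization** (`spotcoloc.coloc`) — the directional statistic:
  Pearson correlation of an anchor gene's expression with the
  neighborhood-averaged expression of a second gene, with a permutation null
  (default 100 shuffles of the averaged gene) and one-sided empirical
  p-values using an add-one pseudocount, assembled into prefiltered pair
  matrices plus BH-adjusted long-format tables.
- **Composition** (`spotcoloc.composition`) — dominant cell type per spot
  (argmax of deconvolution proportions, lexicographic tie-break), enriched
  spot selection by proportion threshold, per-condition label frequencies,
  and a Wilcoxon rank-sum marker filter (exact enumeration for groups of
  <= 10 spots, tie-corrected normal approximation otherwise; Seurat-style
  log2 fold change with |log2FC| > 0.25 gate).
- **Simulator** (`spotcoloc.simulate`) — Visium-like synthetic data with
  ground truth: hexagonal lattice, 1–4 cells per spot mixed by per-domain
  Dirichlet draws, a spatially patchy "infiltrated" disc, negative binomial
  counts with log-normal library sizes, and planted gene pairs whose
  colocalization strength is a tunable effect size (a shared
  Gaussian-smoothed latent field scales both genes' means by
  `exp(gamma * field)`).
- **Pipeline + CLI** (`spotcoloc.pipeline`, `spotcoloc.cli`) — one
  reproducible run per config: read → QC → normalize → graph → coloc +
  composition, each condition handled as an independent slide. Reruns with
  the same config and seed are byte-identical.

## CLI

```sh
# generate a synthetic dataset with ground truth
spotcoloc simulate --seed 1 --out data/sim

# build the Delaunay graph and export its edges
spotcoloc graph --matrix data/sim/matrix.mtx --features data/sim/features.tsv \
    --barcodes data/sim/barcodes.tsv --positions data/sim/positions.csv \
    --out edges.tsv

# all-pairs colocalization
spotcoloc coloc --matrix ... --features ... --barcodes ... --positions ... \
    --row-genes rows.txt --col-genes cols.txt --n-perm 100 --alpha 0.05 \
    --seed 1 --out coloc.tsv

# full pipeline from a YAML config
spotcoloc run --config run.yaml
```

A run config declares per-condition input paths, gene lists, QC thresholds,
`n_perm`, `alpha` and a master seed; see `tests/test_pipeline.py` for a
complete example.

## Notes

- The QC thresholds use **strict** inequalities: spots at exactly 500 UMIs
  or exactly 300 genes are removed.
- The colocalization statistic is **not symmetric**: gene A (column/anchor)
  keeps its raw per-spot values, gene B (row) is neighborhood-averaged.
- The shuffle null does not preserve spatial autocorrelation; spatially
  restricted permutations are out of scope and the empirical p-values
  should be read accordingly.
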