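# zonemark

Cross-species spatial-transcriptomics zonation analysis. Given 10x-style
spot×gene count matrices for two species and an ortholog table mapping one
species' gene symbols onto the other's, the package:

1. applies QC filters (in-tissue spots; genes detected in ≥ 1% of spots),
2. harmonizes gene symbols through the ortholog map (unmapped genes
   dropped; duplicate targets suffixed `.1`, `.2`, …),
3. log-normalizes (CP10k), selects variable genes, embeds both species
   jointly (PCA over the scaled, stacked shared-gene matrix), builds a
   shared-nearest-neighbor Jaccard graph and partitions it with Leiden
   clustering (resolution 0.4 by default),
4. ranks conserved per-cluster marker genes: per-species one-vs-rest
   Wilcoxon rank-sum tests, Tippett minimum-p combination across species,
   both-species filters (log2FC > 1, pct.1 > 0.1), and the ranking score
   `rang = (−log2 minimump_p_val) × (pct.1 sum) × (mean log2FC)`,
5. quantifies how specifically a cross-species gene signature marks one
   cluster: bin-matched module scores, ROC/AUC, Spearman correlations of
   per-cluster log2FC profiles, the specificity margin Δρ, and an
   empirical p-value from random same-sized gene sets (5000 × 18 by
   default).

A seeded synthetic two-species generator (concentric anatomical zones,
negative-binomial counts, planted conserved / species-specific markers and
a shared inner-zone signature) exercises the whole pipeline without any
download.

## CLI

```sh
zonemark simulate --seed 1 --out sim/            # write a synthetic dataset
zonemark run --config run.cfg --seed 1 --out out/  # full pipeline
zonemark cluster --seed 1 --out out/             # stop after clustering
zonemark markers --config run.cfg                # stop after marker ranking
```

Configs are flat `key = value` text with dotted keys for the specificity
block:

```ini
path_a = sim/speciesA          # or "simulate"
path_b = sim/speciesB
ortholog_map = sim/ortholog_map.tsv
min_gene_fraction = 0.01
n_components = 30
resolution = 0.4
specificity.n_perm = 5000
specificity.set_size = 18
seed = 1
```

Outputs per run: `markers_<cluster>.tsv` (per-species statistics,
`max_pval`, `minimump_p_val`, `sum`, `sumLog`, `rang`), `dotplot.tsv`,
`labels.tsv`, optional `spatial_<gene>.tsv`, `specificity.json` (+
permutation vector TSV), `manifest.json` and `run.log`. Identical config
and seed reproduce all tables byte-identically.

## Layout

- `src/zonemark/simulate.py` — synthetic two-species generator + truth tables
- `src/zonemark/io.py` — MatrixMarket/TSV/positions readers and writers, QC
  filters, ortholog mapping
- `src/zonemark/preprocess.py` — normalization, variable genes, joint PCA,
  SNN graph, Leiden clustering
- `src/zonemark/markers.py` — per-cluster DE, meta-p combination,
  conservation filters and ranking
- `src/zonemark/specificity.py` — module score, AUC, profile correlations,
  Δρ, permutation test
- `src/zonemark/pipeline.py`, `cli.py` — orchestration, config, CLI
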