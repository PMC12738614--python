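"""End-to-end orchestration: config parsing, stage wiring, report output.

Config files are flat ``key = value`` text with one nesting level via
dotted keys (``specificity.n_perm = 5000``).  Every numeric default
matches the analysis constants used throughout the package.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from zonemark import __version__, io, markers, preprocess, simulate, specificity

logger = logging.getLogger(__name__)


@dataclass
class SpecificityConfig:
    signature: str = ""  # path: one gene symbol per line; empty -> generator truth
    set_size: int = 18
    n_perm: int = 5000
    n_bins: int = 24
    n_ctrl: int = 100
    target_cluster: str = "INNER"
    reference_cluster: str = ""
    scoring_species: str = "b"  # score the mapped (mouse-role) species


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults mirror the analysis constants."""

    path_a: str = "simulate"
    path_b: str = "simulate"
    ortholog_map: str = ""
    species_a: str = simulate.SPECIES_A
    species_b: str = simulate.SPECIES_B
    scale_factor: float = 1e4
    min_gene_fraction: float = 0.01
    n_hvg: int = 2000
    n_components: int = 30
    knn_k: int = 20
    prune: float = 1.0 / 15.0
    resolution: float = 0.4
    min_log2fc: float = 1.0
    min_pct: float = 0.1
    pseudocount: float = 1.0
    adjust: str = "bonferroni"
    top_n_dotplot: int = 40
    labels: str = ""  # optional TSV (barcode, cluster) bypassing clustering
    use_truth_labels: bool = False  # simulated runs: take labels from truth zones
    spatial_genes: str = ""  # comma-separated symbols -> spatial_<gene>.tsv
    seed: int = 0
    out: str = "zonemark_out"
    specificity: SpecificityConfig = field(default_factory=SpecificityConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_gene_fraction <= 1.0:
            raise ValueError("min_gene_fraction must be in [0, 1]")
        for name in ("scale_factor", "resolution", "n_components", "knn_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _coerce(current, raw: str):
    if isinstance(current, bool):
        return raw.strip().lower() in ("1", "true", "yes")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw.strip()


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file with dotted nesting."""
    config = PipelineConfig()
    known = {f.name for f in fields(config)}
    spec_known = {f.name for f in fields(config.specificity)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key.startswith("specificity."):
            sub = key.split(".", 1)[1]
            if sub not in spec_known:
                raise KeyError(f"{path}:{lineno}: unknown key {key!r}")
            setattr(
                config.specificity,
                sub,
                _coerce(getattr(config.specificity, sub), raw),
            )
        elif key in known and key != "specificity":
            setattr(config, key, _coerce(getattr(config, key), raw))
        else:
            raise KeyError(f"{path}:{lineno}: unknown key {key!r}")
    config.__post_init__()
    return config


def dump_config(config: PipelineConfig) -> str:
    lines = []
    for f in fields(config):
        if f.name == "specificity":
            continue
        lines.append(f"{f.name} = {getattr(config, f.name)}")
    for f in fields(config.specificity):
        lines.append(f"specificity.{f.name} = {getattr(config.specificity, f.name)}")
    return "\n".join(lines) + "\n"


def export_spatial_feature(
    norm: preprocess.NormalizedMatrix,
    positions: pd.DataFrame,
    gene: str,
) -> pd.DataFrame:
    """Per-spot table of one gene's normalized expression with coordinates."""
    if gene not in norm.gene_symbols:
        close = difflib.get_close_matches(gene, norm.gene_symbols, n=3)
        raise KeyError(
            f"gene {gene!r} not in panel; closest matches: {close or 'none'}"
        )
    col = norm.values[:, norm.gene_symbols.index(gene)]
    pos = positions.reindex(norm.barcodes)
    return pd.DataFrame(
        {
            "barcode": norm.barcodes,
            "array_row": pos["array_row"].to_numpy(),
            "array_col": pos["array_col"].to_numpy(),
            "pixel_x": pos["pxl_col"].to_numpy(),
            "pixel_y": pos["pxl_row"].to_numpy(),
            "value": col,
        }
    )


def _load_labels_tsv(path: str | Path) -> preprocess.ClusterLabels:
    table = pd.read_csv(path, sep="\t")
    if not {"barcode", "cluster"}.issubset(table.columns):
        raise ValueError(f"{path}: labels TSV needs 'barcode' and 'cluster' columns")
    raw = table["cluster"].astype(str)
    uniq = sorted(raw.unique())
    index = {name: i for i, name in enumerate(uniq)}
    return preprocess.ClusterLabels(
        labels=np.array([index[c] for c in raw]),
        barcodes=list(table["barcode"].astype(str)),
        species=list(table["species"].astype(str)) if "species" in table else [],
        names={i: name for name, i in index.items()},
    )


def _rename_species_columns(
    ranked: pd.DataFrame, species_a: str, species_b: str
) -> pd.DataFrame:
    """A_/B_ prefixes -> per-species prefixes mirroring the report layout."""
    mapping = {}
    for col in ranked.columns:
        if col.startswith("A_"):
            mapping[col] = f"{species_a}_{col[2:]}"
        elif col.startswith("B_"):
            mapping[col] = f"{species_b}_{col[2:]}"
    return ranked.rename(columns=mapping)


def _prepare_inputs(config: PipelineConfig):
    """Simulate or read both species, QC-filter, and harmonize symbols."""
    bundle = None
    if config.path_a == "simulate" or config.path_b == "simulate":
        bundle = simulate.generate_dataset(simulate.SimConfig(seed=config.seed))
        matrix_a, matrix_b = bundle.matrix_a, bundle.matrix_b
        omap = bundle.ortholog_map
    else:
        if not config.ortholog_map:
            raise ValueError("config key 'ortholog_map' is required for real inputs")
        matrix_a = io.read_10x_dir(config.path_a, species=config.species_a)
        matrix_b = io.read_10x_dir(config.path_b, species=config.species_b)
        omap = io.read_ortholog_map(config.ortholog_map)

    stage_counts = {}
    processed = {}
    for tag, matrix in (("a", matrix_a), ("b", matrix_b)):
        if matrix.positions is not None:
            matrix = io.filter_spots_in_tissue(matrix)
        matrix = io.filter_genes_min_fraction(matrix, config.min_gene_fraction)
        stage_counts[f"species_{tag}_spots"] = matrix.n_spots
        stage_counts[f"species_{tag}_genes_post_filter"] = matrix.n_genes
        processed[tag] = matrix
    processed["b"] = io.apply_ortholog_map(processed["b"], omap)
    stage_counts["species_b_genes_post_ortholog"] = processed["b"].n_genes
    return processed["a"], processed["b"], bundle, stage_counts


STAGES = ("preprocess", "cluster", "markers", "specificity", "all")


def _name_clusters_by_truth(labels, bundle, stage_counts: dict) -> None:
    """Name clusters by the majority planted zone; record the ARI."""
    from sklearn.metrics import adjusted_rand_score

    zone_of = {}
    for layout in bundle.truth.spots.values():
        in_tissue = layout[layout["in_tissue"] == 1]
        zone_of.update(dict(zip(in_tissue["barcode"], in_tissue["zone"])))
    true_zones = [zone_of[b] for b in labels.barcodes]
    stage_counts["clustering_ari_vs_truth"] = float(
        adjusted_rand_score(true_zones, labels.labels)
    )
    for cluster in labels.cluster_ids():
        member_zones = pd.Series(
            [z for z, lab in zip(true_zones, labels.labels) if lab == cluster]
        )
        majority = member_zones.mode().iloc[0]
        name = majority
        suffix = 1
        while name in labels.names.values():
            name = f"{majority}.{suffix}"
            suffix += 1
        labels.names[cluster] = name


def run_pipeline(config: PipelineConfig, stage: str = "all") -> dict:
    """Execute the analysis through ``stage`` and write the report bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("zonemark")
    previous_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    root.addHandler(handler)
    try:
        return _run_pipeline_inner(config, outdir, stage)
    finally:
        root.removeHandler(handler)
        root.setLevel(previous_level)
        handler.close()


def _write_manifest(config: PipelineConfig, outdir: Path, stage_counts, extra=None) -> dict:
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dump_config(config),
        "stage_counts": stage_counts,
        "specificity_summary": extra,
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _run_pipeline_inner(config: PipelineConfig, outdir: Path, stage: str = "all") -> dict:
    matrix_a, matrix_b, bundle, stage_counts = _prepare_inputs(config)

    norm_a = preprocess.log_normalize(matrix_a, config.scale_factor)
    norm_b = preprocess.log_normalize(matrix_b, config.scale_factor)
    shared = sorted(set(norm_a.gene_symbols) & set(norm_b.gene_symbols))
    stage_counts["shared_genes"] = len(shared)
    if not shared:
        raise RuntimeError("normalize: no shared genes after ortholog mapping")
    if stage == "preprocess":
        return _write_manifest(config, outdir, stage_counts)

    if config.labels:
        labels = _load_labels_tsv(config.labels)
        stage_counts["labels_source"] = "file"
    elif config.use_truth_labels and bundle is not None:
        zones = {}
        for layout in bundle.truth.spots.values():
            in_tissue = layout[layout["in_tissue"] == 1]
            zones.update(dict(zip(in_tissue["barcode"], in_tissue["zone"])))
        labels = preprocess.labels_from_zones(
            zones,
            barcodes=list(norm_a.barcodes) + list(norm_b.barcodes),
            species=[config.species_a] * norm_a.n_spots
            + [config.species_b] * norm_b.n_spots,
        )
        stage_counts["labels_source"] = "truth"
    else:
        hvg_pool = [g for g in shared]
        stacked_for_hvg = preprocess.NormalizedMatrix(
            values=np.vstack(
                [
                    norm_a.values[:, norm_a.gene_index(hvg_pool)],
                    norm_b.values[:, norm_b.gene_index(hvg_pool)],
                ]
            ),
            barcodes=list(norm_a.barcodes) + list(norm_b.barcodes),
            gene_symbols=hvg_pool,
            species="joint",
            scale_factor=config.scale_factor,
        )
        hvg = preprocess.select_variable_genes(
            stacked_for_hvg, min(config.n_hvg, len(hvg_pool))
        )
        stage_counts["n_hvg"] = len(hvg)
        embedding = preprocess.joint_pca(
            norm_a, norm_b, hvg, n_components=config.n_components
        )
        graph = preprocess.build_snn_graph(
            embedding, k=config.knn_k, prune=config.prune
        )
        labels = preprocess.cluster_graph(
            graph,
            resolution=config.resolution,
            seed=config.seed,
            barcodes=embedding.barcodes,
            species=embedding.species,
        )
        stage_counts["labels_source"] = "clustering"
        if bundle is not None:
            _name_clusters_by_truth(labels, bundle, stage_counts)
    stage_counts["n_clusters"] = len(labels.cluster_ids())

    labels_table = pd.DataFrame(
        {
            "barcode": labels.barcodes,
            "cluster": [labels.name_of(c) for c in labels.labels],
        }
    )
    if labels.species:
        labels_table["species"] = labels.species
    labels_table.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    if stage == "cluster":
        return _write_manifest(config, outdir, stage_counts)

    norms = {config.species_a: norm_a, config.species_b: norm_b}
    barcodes_a = set(norm_a.barcodes)
    barcodes_b = set(norm_b.barcodes)
    ranked_by_cluster: dict[str, pd.DataFrame] = {}
    for cluster in labels.cluster_ids():
        members = [
            b for b, lab in zip(labels.barcodes, labels.labels) if lab == cluster
        ]
        in_a = sum(b in barcodes_a for b in members)
        in_b = sum(b in barcodes_b for b in members)
        name = labels.name_of(cluster)
        if in_a == 0 or in_b == 0:
            logger.warning(
                "markers: cluster %s present in only one species; skipped", name
            )
            continue
        ranked = markers.conserved_markers_for_cluster(
            norm_a,
            norm_b,
            labels,
            cluster,
            min_log2fc=config.min_log2fc,
            min_pct=config.min_pct,
            pseudocount=config.pseudocount,
            adjust=config.adjust,
        )
        ranked_by_cluster[name] = ranked
        out = _rename_species_columns(ranked, config.species_a, config.species_b)
        out.to_csv(outdir / f"markers_{name.replace('/', '-')}.tsv", sep="\t")
        stage_counts[f"conserved_markers_{name}"] = len(ranked)

    if ranked_by_cluster:
        top = max(ranked_by_cluster.values(), key=lambda df: len(df))
        dotplot = markers.export_dotplot_table(
            top, norms, labels, top_n=config.top_n_dotplot
        )
        dotplot.to_csv(outdir / "dotplot.tsv", sep="\t", index=False)

    for gene in filter(None, (g.strip() for g in config.spatial_genes.split(","))):
        for tag, norm, matrix in (
            (config.species_a, norm_a, matrix_a),
            (config.species_b, norm_b, matrix_b),
        ):
            if gene in norm.gene_symbols and matrix.positions is not None:
                table = export_spatial_feature(norm, matrix.positions, gene)
                table.to_csv(
                    outdir / f"spatial_{gene}_{tag}.tsv", sep="\t", index=False
                )
    if stage == "markers":
        return _write_manifest(config, outdir, stage_counts)

    spec_cfg = config.specificity
    signature: list[str] = []
    if spec_cfg.signature:
        signature = [
            line.strip()
            for line in Path(spec_cfg.signature).read_text().splitlines()
            if line.strip()
        ]
    elif bundle is not None:
        signature = list(bundle.truth.signature)
    report_dict = None
    cluster_names = {labels.name_of(c) for c in labels.cluster_ids()}
    if signature and spec_cfg.target_cluster in cluster_names:
        scored = norm_b if spec_cfg.scoring_species.lower() in ("b", "speciesb") else norm_a
        reference = norm_a if scored is norm_b else norm_b
        report = specificity.run_specificity(
            norm_ref=reference,
            norm_scored=scored,
            labels=labels,
            signature=signature,
            target=spec_cfg.target_cluster,
            reference_cluster=spec_cfg.reference_cluster or None,
            set_size=spec_cfg.set_size,
            n_perm=spec_cfg.n_perm,
            n_bins=spec_cfg.n_bins,
            n_ctrl=spec_cfg.n_ctrl,
            seed=config.seed,
            pseudocount=config.pseudocount,
        )
        report.write(outdir / "specificity.json")
        report_dict = report.to_dict()
        del report_dict["signature"]  # already in manifest config echo
    else:
        logger.warning("specificity stage skipped (no signature or target cluster)")

    return _write_manifest(config, outdir, stage_counts, report_dict)
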