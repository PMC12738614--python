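"""Two-species synthetic Visium-like data with planted zonal markers.

Generates, per species, a lattice of spots partitioned into concentric
anatomical zones, negative-binomial counts with planted zone-enriched
markers (some conserved across species, some species-specific), a
synthetic ortholog map between the two gene panels, and ground-truth
tables for benchmarking the downstream marker and specificity analyses.

The count model is gamma-Poisson (negative binomial):

    count(s, g) ~ NB(mean = baseline(g) * libsize(s) * fold(g, s),
                     size = dispersion)

with fold(g, s) = planted_fold(g) when spot ``s`` lies in gene ``g``'s
home zone (for the species in which the marker is planted) and 1
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from zonemark.io import (
    OrthologMap,
    SpotMatrix,
    write_10x_dir,
    write_ortholog_map,
)

#: zone labels ordered from the lattice center outwards
ZONES = ("MEDULLA", "INNER", "ZF", "ZG", "CTWAT")
NONE_ZONE = "NONE"

SPECIES_A = "speciesA"  # plays the human role (target symbols)
SPECIES_B = "speciesB"  # plays the mouse role (mapped through orthologs)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic two-species dataset."""

    n_rows: int = 31
    n_cols: int = 31
    center: tuple[float, float] | None = None  # defaults to lattice middle
    radii: tuple[float, float, float, float, float] = (3.5, 6.0, 9.5, 12.5, 14.5)
    # off-gland BAT patch for species B: (row0, row1, col0, col1), half-open
    bat_patch: tuple[int, int, int, int] | None = (0, 4, 0, 4)

    n_genes_total: int = 1000
    n_conserved_per_zone: int = 20
    n_specific_per_zone: int = 5  # per species, per zone
    signature_size: int = 18
    shared_signature: bool = True

    fold_min: float = 4.0
    fold_max: float = 16.0
    baseline_log_mean: float = math.log(0.5)
    baseline_log_sd: float = 1.0
    marker_baseline_log_mean: float = math.log(2.0)
    marker_baseline_log_sd: float = 0.5
    dispersion: float = 2.0
    libsize_log_sd: float = 0.35

    ortholog_missing_rate: float = 0.05
    ortholog_duplicate_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if len(radii) != len(ZONES):
            raise ConfigurationError(f"need {len(ZONES)} radii, got {len(radii)}")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ConfigurationError(f"radii must be strictly increasing: {radii}")
        self.radii = radii
        for name in ("ortholog_missing_rate", "ortholog_duplicate_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {rate}")
        if self.fold_min < 1.0 or self.fold_max < self.fold_min:
            raise ConfigurationError("fold range must satisfy 1 <= fold_min <= fold_max")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigurationError("lattice must be nonempty")
        needed = len(ZONES) * (self.n_conserved_per_zone + 2 * self.n_specific_per_zone)
        if needed > self.n_genes_total:
            raise ConfigurationError(
                f"{needed} planted genes exceed n_genes_total={self.n_genes_total}"
            )


@dataclass
class SimTruth:
    """Ground truth: per-gene planting and per-spot zone assignments."""

    genes: pd.DataFrame  # symbol_a, symbol_b, home_zone, conserved, fold_a, fold_b, ...
    spots: dict[str, pd.DataFrame] = field(default_factory=dict)  # species -> layout
    signature: list[str] = field(default_factory=list)  # species-A symbols


@dataclass
class SimBundle:
    matrix_a: SpotMatrix
    matrix_b: SpotMatrix
    ortholog_map: OrthologMap
    truth: SimTruth
    config: SimConfig


def build_zone_layout(config: SimConfig, species: str) -> pd.DataFrame:
    """Assign every lattice spot to a concentric zone (or NONE, off-tissue).

    Distance thresholds are half-open: a spot at Euclidean distance ``d``
    from the center gets the innermost zone whose radius exceeds ``d``.
    For ``SPECIES_B`` an off-gland rectangular patch is carved out as
    INNER tissue (brown adipose abutting the gland).
    """
    rows, cols = np.meshgrid(
        np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij"
    )
    rows = rows.ravel()
    cols = cols.ravel()
    center = config.center or ((config.n_rows - 1) / 2.0, (config.n_cols - 1) / 2.0)
    dist = np.hypot(rows - center[0], cols - center[1])

    zone = np.full(rows.shape, NONE_ZONE, dtype=object)
    lower = 0.0
    for name, radius in zip(ZONES, config.radii):
        zone[(dist >= lower) & (dist < radius)] = name
        lower = radius

    if species == SPECIES_B and config.bat_patch is not None:
        r0, r1, c0, c1 = config.bat_patch
        patch = (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)
        zone[patch & (zone == NONE_ZONE)] = "INNER"

    layout = pd.DataFrame(
        {
            "barcode": [
                f"{species}_R{r:03d}C{c:03d}-1" for r, c in zip(rows, cols)
            ],
            "in_tissue": (zone != NONE_ZONE).astype(int),
            "array_row": rows,
            "array_col": cols,
            "pxl_row": rows * 100.0,
            "pxl_col": cols * 100.0,
            "zone": zone,
        }
    )
    return layout.set_index("barcode", drop=False)


def build_gene_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the gene panel: symbols, baselines, planted zones and folds.

    Concepts are shared across species: concept ``i`` appears as
    ``GENE<i>`` in species A and ``geneb<i>`` in species B, with a common
    baseline mean.  Planted markers carry a multiplicative fold in their
    home zone, either in both species (conserved) or in one.
    """
    n = config.n_genes_total
    genes = pd.DataFrame(
        {
            "symbol_a": [f"GENE{i:05d}" for i in range(n)],
            "symbol_b": [f"geneb{i:05d}" for i in range(n)],
            "home_zone": "",
            "conserved": False,
            "fold_a": 1.0,
            "fold_b": 1.0,
            "in_signature": False,
        }
    )
    genes["baseline_mean"] = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=n
    )

    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + k)
        cursor += k
        return idx

    def plant(idx: np.ndarray, zone: str, species: str | None) -> None:
        folds = rng.uniform(config.fold_min, config.fold_max, size=len(idx))
        genes.loc[idx, "home_zone"] = zone
        genes.loc[idx, "baseline_mean"] = rng.lognormal(
            config.marker_baseline_log_mean,
            config.marker_baseline_log_sd,
            size=len(idx),
        )
        if species is None:
            genes.loc[idx, ["fold_a", "fold_b"]] = np.column_stack([folds, folds])
            genes.loc[idx, "conserved"] = True
        elif species == SPECIES_A:
            genes.loc[idx, "fold_a"] = folds
        else:
            genes.loc[idx, "fold_b"] = folds

    for zone in ZONES:
        conserved_idx = take(config.n_conserved_per_zone)
        if zone == "INNER" and not config.shared_signature:
            # null configuration: the would-be shared inner signature is
            # replaced by independent species-specific inner markers
            half = len(conserved_idx) // 2
            plant(conserved_idx[:half], zone, SPECIES_A)
            plant(conserved_idx[half:], zone, SPECIES_B)
        else:
            plant(conserved_idx, zone, None)
            if zone == "INNER":
                sig = conserved_idx[: config.signature_size]
                genes.loc[sig, "in_signature"] = True
        plant(take(config.n_specific_per_zone), zone, SPECIES_A)
        plant(take(config.n_specific_per_zone), zone, SPECIES_B)

    return genes


def build_synthetic_ortholog_map(
    truth: SimTruth | pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> OrthologMap:
    """Map species-B symbols onto species-A symbols with dropout/duplication.

    Each species-B gene keeps its mapping with probability
    ``1 - ortholog_missing_rate``.  Independently, with probability
    ``ortholog_duplicate_rate`` a mapped gene spawns a second species-B
    source (suffix ``alt``) mapped onto the same species-A symbol,
    flagged as a duplicate target.
    """
    genes = truth.genes if isinstance(truth, SimTruth) else truth
    sources: list[str] = []
    targets: list[str] = []
    flags: list[bool] = []
    keep = rng.random(len(genes)) >= config.ortholog_missing_rate
    dup = rng.random(len(genes)) < config.ortholog_duplicate_rate
    for (symbol_b, symbol_a), kept, duplicated in zip(
        zip(genes["symbol_b"], genes["symbol_a"]), keep, dup
    ):
        if not kept:
            continue
        sources.append(symbol_b)
        targets.append(symbol_a)
        flags.append(False)
        if duplicated:
            sources.append(symbol_b + "alt")
            targets.append(symbol_a)
            flags.append(True)
    return OrthologMap(
        pairs=pd.DataFrame(
            {"source": sources, "target": targets, "is_duplicate_target": flags}
        )
    )


def simulate_species_counts(
    layout: pd.DataFrame,
    truth: SimTruth | pd.DataFrame,
    config: SimConfig,
    species: str,
    rng: np.random.Generator,
    extra_genes: list[str] | None = None,
) -> SpotMatrix:
    """Sample negative-binomial counts for one species over its layout.

    ``extra_genes`` appends species-B-only background genes (duplicate
    ortholog sources) with freshly drawn baselines and no planted fold.
    """
    if layout.empty:
        raise ValueError("empty layout")
    genes = truth.genes if isinstance(truth, SimTruth) else truth
    symbol_col = "symbol_a" if species == SPECIES_A else "symbol_b"
    fold_col = "fold_a" if species == SPECIES_A else "fold_b"

    symbols = list(genes[symbol_col])
    baseline = genes["baseline_mean"].to_numpy(dtype=float)
    fold = genes[fold_col].to_numpy(dtype=float)
    home = genes["home_zone"].to_numpy(dtype=object)

    planted_zones = set(home[fold > 1.0])
    present = set(layout["zone"])
    missing_zones = planted_zones - present
    if missing_zones:
        raise ValueError(f"planted home zones absent from layout: {missing_zones}")

    if extra_genes:
        symbols = symbols + list(extra_genes)
        baseline = np.concatenate(
            [
                baseline,
                rng.lognormal(
                    config.baseline_log_mean,
                    config.baseline_log_sd,
                    size=len(extra_genes),
                ),
            ]
        )
        fold = np.concatenate([fold, np.ones(len(extra_genes))])
        home = np.concatenate([home, np.full(len(extra_genes), "", dtype=object)])

    n_spots = len(layout)
    n_genes = len(symbols)
    libsize = rng.lognormal(0.0, config.libsize_log_sd, size=n_spots)

    mean = np.outer(libsize, baseline)
    zones = layout["zone"].to_numpy(dtype=object)
    for zone in planted_zones:
        in_zone = zones == zone
        boosted = (home == zone) & (fold > 1.0)
        mean[np.ix_(in_zone, boosted)] *= fold[boosted]

    # gamma-Poisson mixture == negative binomial with size = dispersion
    lam = rng.gamma(shape=config.dispersion, scale=mean / config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    return SpotMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=list(layout["barcode"]),
        gene_symbols=symbols,
        species=species,
        positions=layout,
    )


def generate_dataset(config: SimConfig) -> SimBundle:
    """Generate the full two-species bundle deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    genes = build_gene_truth(config, rng)
    truth = SimTruth(genes=genes)
    truth.signature = list(genes.loc[genes["in_signature"], "symbol_a"])

    omap = build_synthetic_ortholog_map(truth, config, rng)
    base_b = set(genes["symbol_b"])
    extra = [s for s in omap.pairs["source"] if s not in base_b]

    layout_a = build_zone_layout(config, SPECIES_A)
    layout_b = build_zone_layout(config, SPECIES_B)
    in_a = layout_a[layout_a["in_tissue"] == 1]
    in_b = layout_b[layout_b["in_tissue"] == 1]
    truth.spots = {SPECIES_A: layout_a, SPECIES_B: layout_b}

    matrix_a = simulate_species_counts(in_a, truth, config, SPECIES_A, rng)
    matrix_a.positions = layout_a
    matrix_b = simulate_species_counts(
        in_b, truth, config, SPECIES_B, rng, extra_genes=extra
    )
    matrix_b.positions = layout_b
    return SimBundle(
        matrix_a=matrix_a,
        matrix_b=matrix_b,
        ortholog_map=omap,
        truth=truth,
        config=config,
    )


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Configuration with no shared inner signature (calibration null)."""
    return SimConfig(seed=seed, shared_signature=False, **overrides)


def write_dataset(bundle: SimBundle, outdir: str | Path) -> Path:
    """Write the bundle in the formats the I/O module reads, plus truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_10x_dir(bundle.matrix_a, outdir / SPECIES_A)
    write_10x_dir(bundle.matrix_b, outdir / SPECIES_B)
    write_ortholog_map(bundle.ortholog_map, outdir / "ortholog_map.tsv")
    bundle.truth.genes.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)
    spot_truth = pd.concat(
        [
            table.assign(species=species)
            for species, table in bundle.truth.spots.items()
        ]
    )
    spot_truth.to_csv(outdir / "spot_truth.tsv", sep="\t", index=False)
    (outdir / "signature.txt").write_text(
        "".join(g + "\n" for g in bundle.truth.signature)
    )
    lines = []
    for key, value in asdict(bundle.config).items():
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}\n")
    (outdir / "config.txt").write_text("".join(lines))
    return outdir
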