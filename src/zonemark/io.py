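"""Reading and writing 10x-style spatial files, QC filters, ortholog mapping.

The canonical interchange format is the MatrixMarket triplet
(matrix.mtx[.gz] + barcodes.tsv[.gz] + features.tsv[.gz]) with an optional
tissue-positions CSV.  The matrix file stores genes x barcodes (the 10x
convention); :class:`SpotMatrix` holds spots as rows.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row",
    "pxl_col",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared dialect."""


@dataclass
class SpotMatrix:
    """Raw integer counts for one species: spots x genes.

    Attributes
    ----------
    counts
        CSR sparse matrix of non-negative integers, spots as rows.
    barcodes
        Unique spot barcodes, one per row.
    gene_symbols
        Unique gene symbols, one per column.
    species
        Free-form species tag (e.g. ``"human"``).
    positions
        Optional per-spot table with the columns in
        :data:`POSITION_COLUMNS` plus an optional ``zone`` column,
        indexed like ``barcodes``.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    gene_symbols: list[str]
    species: str = ""
    positions: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = list(self.barcodes)
        self.gene_symbols = list(self.gene_symbols)
        n_spots, n_genes = self.counts.shape
        if len(self.barcodes) != n_spots:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {n_spots} matrix rows"
            )
        if len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} matrix columns"
            )
        if len(set(self.barcodes)) != n_spots:
            raise FormatError("barcodes are not unique")
        if len(set(self.gene_symbols)) != n_genes:
            raise FormatError("gene symbols are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class OrthologMap:
    """Gene-symbol translation table between two species' panels.

    ``pairs`` maps each unique source symbol to a target symbol; targets
    may repeat only when the pair is flagged as a duplicate target.
    """

    pairs: pd.DataFrame  # columns: source, target, is_duplicate_target

    def __post_init__(self) -> None:
        required = {"source", "target", "is_duplicate_target"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValueError(f"ortholog map missing columns: {sorted(missing)}")
        if self.pairs["source"].duplicated().any():
            raise ValueError("ortholog map source symbols must be unique")
        dup_targets = self.pairs["target"].duplicated(keep=False)
        bad = dup_targets & ~self.pairs["is_duplicate_target"]
        # the first occurrence of a duplicated target keeps its plain name,
        # so only repeats beyond the first need the flag
        first = ~self.pairs["target"].duplicated(keep="first")
        if (bad & ~first).any():
            raise ValueError("repeated targets must be flagged is_duplicate_target")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["source"], self.pairs["target"]))


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_component(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        candidate = directory / name
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def read_10x_dir(path: str | Path, species: str = "") -> SpotMatrix:
    """Read a 10x-style directory into a :class:`SpotMatrix`.

    Expects matrix.mtx, barcodes.tsv and features.tsv (each optionally
    gzipped); tissue_positions_list.csv is attached when present.  The
    MatrixMarket file stores genes x barcodes and is transposed so spots
    become rows.  The features file may have 1-3 columns (id, symbol,
    type); the symbol column is used, falling back to the id.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    mtx_path = _find_component(directory, "matrix.mtx")
    barcodes_path = _find_component(directory, "barcodes.tsv")
    features_path = _find_component(directory, "features.tsv")

    with _open_maybe_gz(mtx_path) as handle:
        matrix = scipy.io.mmread(handle)
    matrix = sp.csr_matrix(matrix.T)  # genes x barcodes on disk
    if matrix.nnz:
        matrix.data = np.rint(matrix.data).astype(np.int64)
        matrix.eliminate_zeros()

    with _open_maybe_gz(barcodes_path) as handle:
        barcodes = [line.strip().split("\t")[0] for line in handle if line.strip()]
    with _open_maybe_gz(features_path) as handle:
        rows = [line.rstrip("\n").split("\t") for line in handle if line.strip()]
    symbols = [row[1] if len(row) >= 2 else row[0] for row in rows]

    if matrix.shape[0] != len(barcodes) or matrix.shape[1] != len(symbols):
        raise FormatError(
            f"matrix is {matrix.shape[1]} genes x {matrix.shape[0]} barcodes but "
            f"features.tsv has {len(symbols)} rows and barcodes.tsv {len(barcodes)}"
        )

    positions = None
    for name in ("tissue_positions_list.csv", "tissue_positions.csv"):
        if (directory / name).exists():
            positions = read_tissue_positions(directory / name)
            break

    return SpotMatrix(
        counts=matrix,
        barcodes=barcodes,
        gene_symbols=symbols,
        species=species,
        positions=positions,
    )


def read_tissue_positions(path: str | Path) -> pd.DataFrame:
    """Read a tissue-positions CSV (6 columns, header optional)."""
    path = Path(path)
    first = pd.read_csv(path, header=None, nrows=1)
    if first.shape[1] != 6:
        raise FormatError(
            f"{path.name}: expected 6 columns, found {first.shape[1]}"
        )
    # header row detected when the second field is not parseable as int
    has_header = not str(first.iloc[0, 1]).strip().lstrip("-").isdigit()
    table = pd.read_csv(path, header=0 if has_header else None)
    table.columns = POSITION_COLUMNS
    table["in_tissue"] = table["in_tissue"].astype(int)
    return table.set_index("barcode", drop=False)


def write_tissue_positions(positions: pd.DataFrame, path: str | Path) -> None:
    positions.loc[:, POSITION_COLUMNS].to_csv(path, header=False, index=False)


def write_10x_dir(matrix: SpotMatrix, path: str | Path, gzip_mtx: bool = False) -> Path:
    """Write ``matrix`` as a 10x-style directory (genes x barcodes mtx)."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)

    genes_by_barcodes = sp.coo_matrix(matrix.counts.T)
    mtx_name = "matrix.mtx.gz" if gzip_mtx else "matrix.mtx"
    target = directory / mtx_name
    opener = gzip.open if gzip_mtx else open
    with opener(target, "wb") as handle:
        scipy.io.mmwrite(handle, genes_by_barcodes, field="integer")

    (directory / "barcodes.tsv").write_text(
        "".join(b + "\n" for b in matrix.barcodes)
    )
    (directory / "features.tsv").write_text(
        "".join(
            f"{symbol}\t{symbol}\tGene Expression\n"
            for symbol in matrix.gene_symbols
        )
    )
    if matrix.positions is not None:
        write_tissue_positions(
            matrix.positions, directory / "tissue_positions_list.csv"
        )
    return directory


def filter_spots_in_tissue(matrix: SpotMatrix) -> SpotMatrix:
    """Keep only spots flagged in_tissue in the positions table, in order."""
    if matrix.positions is None:
        raise ValueError("no positions table loaded; cannot filter by tissue")
    flags = (
        matrix.positions.reindex(matrix.barcodes)["in_tissue"]
        .fillna(0)
        .astype(int)
        .to_numpy()
    )
    keep = flags == 1
    if not keep.any():
        raise ValueError("no spots remain after in-tissue filtering")
    kept_barcodes = [b for b, k in zip(matrix.barcodes, keep) if k]
    return replace(
        matrix,
        counts=matrix.counts[keep],
        barcodes=kept_barcodes,
        positions=matrix.positions.reindex(kept_barcodes),
    )


def filter_genes_min_fraction(
    matrix: SpotMatrix, min_fraction: float = 0.01
) -> SpotMatrix:
    """Keep genes detected (count > 0) in at least ``min_fraction`` of spots.

    The boundary is inclusive: a gene detected in exactly
    ``min_fraction * n_spots`` spots is retained.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    detected = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    keep = detected >= min_fraction * matrix.n_spots
    logger.info(
        "gene filter (>= %.2f%% of %d spots): %d of %d genes retained",
        100 * min_fraction,
        matrix.n_spots,
        int(keep.sum()),
        matrix.n_genes,
    )
    return replace(
        matrix,
        counts=sp.csr_matrix(matrix.counts[:, keep]),
        gene_symbols=[g for g, k in zip(matrix.gene_symbols, keep) if k],
    )


def apply_ortholog_map(matrix: SpotMatrix, mapping: OrthologMap) -> SpotMatrix:
    """Translate gene symbols through an ortholog map.

    Genes without a mapping are dropped.  When several source genes map
    to one target symbol, the second and subsequent occurrences (in input
    column order) get deterministic suffixes ``.1``, ``.2``, ...  Counts
    are never merged.
    """
    lookup = mapping.as_dict()
    if not lookup:
        warnings.warn("empty ortholog map: all genes dropped", stacklevel=2)
    keep_idx: list[int] = []
    new_symbols: list[str] = []
    seen: dict[str, int] = {}
    for idx, symbol in enumerate(matrix.gene_symbols):
        target = lookup.get(symbol)
        if target is None:
            continue
        occurrence = seen.get(target, 0)
        seen[target] = occurrence + 1
        keep_idx.append(idx)
        new_symbols.append(target if occurrence == 0 else f"{target}.{occurrence}")
    return replace(
        matrix,
        counts=sp.csr_matrix(matrix.counts[:, keep_idx]),
        gene_symbols=new_symbols,
    )


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a 2-3 column TSV: source, target[, is_duplicate_target]."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs at least 2 columns")
    # tolerate a header line
    if table.iloc[0, 0].lower() in ("source", "source_symbol"):
        table = table.iloc[1:].reset_index(drop=True)
    pairs = pd.DataFrame(
        {
            "source": table.iloc[:, 0],
            "target": table.iloc[:, 1],
            "is_duplicate_target": (
                table.iloc[:, 2].astype(str).str.lower().isin(("1", "true"))
                if table.shape[1] >= 3
                else False
            ),
        }
    )
    return OrthologMap(pairs=pairs)


def write_ortholog_map(mapping: OrthologMap, path: str | Path) -> None:
    out = mapping.pairs.copy()
    out["is_duplicate_target"] = out["is_duplicate_target"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)
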