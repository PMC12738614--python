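"""Normalization, variable-gene selection, joint embedding and clustering.

Cross-species integration is deliberately simple: the two species'
normalized matrices are stacked over their shared (ortholog-mapped)
genes, each gene is centered and unit-scaled across the stacked matrix,
and PCA / SNN / Leiden run on the joint embedding.  Cluster labels may
alternatively be supplied externally (e.g. from a generator truth table)
to bypass clustering entirely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from zonemark.io import SpotMatrix

logger = logging.getLogger(__name__)

DEFAULT_SCALE_FACTOR = 1e4
DEFAULT_N_COMPONENTS = 30
DEFAULT_KNN_K = 20
DEFAULT_PRUNE = 1.0 / 15.0
DEFAULT_RESOLUTION = 0.4


@dataclass
class NormalizedMatrix:
    """Log-normalized expression (natural log of 1 + CP-scale counts)."""

    values: np.ndarray  # spots x genes, dense
    barcodes: list[str]
    gene_symbols: list[str]
    species: str = ""
    scale_factor: float = DEFAULT_SCALE_FACTOR

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def gene_index(self, symbols: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_symbols)}
        try:
            return np.array([lookup[s] for s in symbols], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene not in panel: {exc.args[0]}") from exc


@dataclass
class Embedding:
    coordinates: np.ndarray  # spots x n_components
    explained_variance: np.ndarray
    barcodes: list[str]
    species: list[str]

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance)
        if np.any(np.diff(ev) > 1e-9):
            raise ValueError("explained_variance must be non-increasing")


@dataclass
class ClusterLabels:
    """Partition of spots into integer-labelled clusters."""

    labels: np.ndarray  # int per spot
    barcodes: list[str]
    species: list[str] = field(default_factory=list)
    resolution: float = DEFAULT_RESOLUTION
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.barcodes):
            raise ValueError("one label per barcode required")

    def cluster_ids(self) -> list[int]:
        return sorted(set(self.labels.tolist()))

    def name_of(self, cluster: int) -> str:
        return self.names.get(cluster, str(cluster))

    def subset(self, mask: np.ndarray) -> "ClusterLabels":
        return ClusterLabels(
            labels=self.labels[mask],
            barcodes=[b for b, m in zip(self.barcodes, mask) if m],
            species=[s for s, m in zip(self.species, mask) if m] if self.species else [],
            resolution=self.resolution,
            names=dict(self.names),
        )


def log_normalize(
    matrix: SpotMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NormalizedMatrix:
    """value(s, g) = ln(1 + count(s, g) / total(s) * scale_factor).

    Spots with zero total are left all-zero (with a warning).
    """
    counts = matrix.to_dense().astype(float)
    if counts.size and counts.min() < 0:
        raise ValueError("negative counts")
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} spots have zero total counts; left as zeros",
            stacklevel=2,
        )
    safe_totals = np.where(zero, 1.0, totals)
    values = np.log1p(counts / safe_totals[:, None] * scale_factor)
    return NormalizedMatrix(
        values=values,
        barcodes=list(matrix.barcodes),
        gene_symbols=list(matrix.gene_symbols),
        species=matrix.species,
        scale_factor=scale_factor,
    )


def select_variable_genes(
    norm: NormalizedMatrix, n_top: int, clip: float | None = None
) -> list[str]:
    """Rank genes by variance standardized against a mean-variance trend.

    A quadratic trend of log10-variance on log10-mean is fitted over
    genes with positive variance; each gene's values are standardized by
    the trend-predicted standard deviation, clipped (default sqrt(n)),
    and re-ranked by the variance of the clipped standardized values.
    Ties break by symbol order.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    n_genes = len(norm.gene_symbols)
    if n_top > n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds panel size {n_genes}; returning all genes",
            stacklevel=2,
        )
        n_top = n_genes

    values = norm.values
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(n_genes)
    positive = (var > 0) & (mean > 0)

    expected_var = np.full(n_genes, np.nan)
    if positive.sum() >= 3:
        coeffs = np.polyfit(np.log10(mean[positive]), np.log10(var[positive]), deg=2)
        expected_var[positive] = 10 ** np.polyval(coeffs, np.log10(mean[positive]))
    else:
        # too few genes to fit a trend: flat trend keeps the raw ordering
        expected_var[positive] = var[positive].mean()

    clip_value = clip if clip is not None else np.sqrt(values.shape[0])
    score = np.zeros(n_genes)
    for j in np.flatnonzero(positive):
        z = (values[:, j] - mean[j]) / np.sqrt(expected_var[j])
        z = np.clip(z, -clip_value, clip_value)
        score[j] = z.var(ddof=1)

    order = sorted(range(n_genes), key=lambda j: (-score[j], norm.gene_symbols[j]))
    return [norm.gene_symbols[j] for j in order[:n_top]]


def joint_pca(
    norm_a: NormalizedMatrix,
    norm_b: NormalizedMatrix,
    genes: list[str],
    n_components: int = DEFAULT_N_COMPONENTS,
    scale_max: float = 10.0,
) -> Embedding:
    """PCA of the stacked two-species matrix over shared genes.

    Each gene is centered and unit-scaled across the stacked matrix,
    with standardized values clipped at ``scale_max`` before the
    decomposition.
    """
    idx_a = norm_a.gene_index(genes)
    idx_b = norm_b.gene_index(genes)
    stacked = np.vstack([norm_a.values[:, idx_a], norm_b.values[:, idx_b]])
    n_spots, n_genes = stacked.shape

    limit = min(n_spots, n_genes)
    if n_components > limit:
        warnings.warn(
            f"n_components={n_components} reduced to {limit}", stacklevel=2
        )
        n_components = limit

    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    scaled = np.clip((stacked - mean) / std, -scale_max, scale_max)
    scaled -= scaled.mean(axis=0)  # re-center after clipping

    u, s, vt = np.linalg.svd(scaled, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u[:, :n_components] * s[:n_components]
    explained = (s[:n_components] ** 2) / max(n_spots - 1, 1)

    return Embedding(
        coordinates=coords,
        explained_variance=explained,
        barcodes=list(norm_a.barcodes) + list(norm_b.barcodes),
        species=[norm_a.species] * norm_a.n_spots + [norm_b.species] * norm_b.n_spots,
    )


def build_snn_graph(
    embedding: Embedding, k: int = DEFAULT_KNN_K, prune: float = DEFAULT_PRUNE
) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each spot's neighbor set is its ``k`` nearest Euclidean neighbors in
    the embedding, self included.  Edge weight(i, j) =
    |N(i) ∩ N(j)| / |N(i) ∪ N(j)|; edges below ``prune`` are removed.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    coords = embedding.coordinates
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots ({n})")

    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, indices = nn.kneighbors(coords)  # includes self (distance 0)

    rows = np.repeat(np.arange(n), k)
    membership = sp.csr_matrix(
        (np.ones(n * k), (rows, indices.ravel())), shape=(n, n)
    )
    membership.data = np.minimum(membership.data, 1.0)  # guard duplicate points
    shared = (membership @ membership.T).tocoo()

    mask = shared.row < shared.col
    i, j, inter = shared.row[mask], shared.col[mask], shared.data[mask]
    sizes = np.asarray(membership.sum(axis=1)).ravel()
    union = sizes[i] + sizes[j] - inter
    jaccard = inter / union
    keep = jaccard >= prune

    graph = ig.Graph(
        n=n,
        edges=list(zip(i[keep].tolist(), j[keep].tolist())),
        edge_attrs={"weight": jaccard[keep].tolist()},
    )
    graph.vs["name"] = embedding.barcodes
    return graph


def cluster_graph(
    graph: ig.Graph,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
    barcodes: list[str] | None = None,
    species: list[str] | None = None,
) -> ClusterLabels:
    """Leiden modularity clustering; labels renumbered by decreasing size."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if graph.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.array(partition.membership)
    order = np.argsort(-np.bincount(raw), kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(x)] for x in raw])

    if barcodes is None:
        barcodes = list(graph.vs["name"]) if "name" in graph.vs.attributes() else [
            str(i) for i in range(graph.vcount())
        ]
    logger.info(
        "clustering at resolution %.2f: %d clusters over %d spots",
        resolution,
        labels.max() + 1,
        len(labels),
    )
    return ClusterLabels(
        labels=labels,
        barcodes=barcodes,
        species=list(species) if species is not None else [],
        resolution=resolution,
    )


def labels_from_zones(
    zones: pd.Series | dict[str, str],
    barcodes: list[str],
    species: list[str] | None = None,
) -> ClusterLabels:
    """Build cluster labels directly from a spot -> zone mapping."""
    mapping = zones if isinstance(zones, dict) else zones.to_dict()
    zone_of = [mapping[b] for b in barcodes]
    uniq = sorted(set(zone_of))
    index = {z: i for i, z in enumerate(uniq)}
    return ClusterLabels(
        labels=np.array([index[z] for z in zone_of]),
        barcodes=list(barcodes),
        species=list(species) if species is not None else [],
        names={i: z for z, i in index.items()},
    )
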