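"""Per-cluster differential expression and cross-species conserved ranking.

For one species, every gene is tested one-vs-rest per cluster with a
two-sided Wilcoxon rank-sum test on the log-normalized values.  Across
species, p-values are combined by Tippett's minimum-p rule, candidates
are filtered on fold change and detection fraction in both species, and
survivors are ranked by

    rang = (-log2(minimump_p_val)) * (pct_1_a + pct_1_b)
           * mean(log2FC_a, log2FC_b)

sorted descending.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from zonemark.preprocess import ClusterLabels, NormalizedMatrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
EXACT_GROUP_LIMIT = 25
ENUMERATION_LIMIT = 200_000

SPECIES_STAT_COLUMNS = ("p_val", "avg_log2FC", "pct.1", "pct.2", "p_val_adj")


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, exact_limit: int = EXACT_GROUP_LIMIT
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for one gene.

    Exact when both groups have at most ``exact_limit`` observations:
    via the tie-free exact distribution, or full enumeration of group
    assignments with midranks when ties are present (falling back to the
    normal approximation if the enumeration would be too large).  The
    asymptotic path uses the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")

    small = len(x) <= exact_limit and len(y) <= exact_limit
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if small and not has_ties:
        return float(scipy.stats.mannwhitneyu(x, y, method="exact").pvalue)
    if small and has_ties:
        if math.comb(len(pooled), len(x)) <= ENUMERATION_LIMIT:
            return _exact_enumeration_p(x, y)
    return float(
        scipy.stats.mannwhitneyu(
            x, y, method="asymptotic", use_continuity=True
        ).pvalue
    )


def _exact_enumeration_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all group assignments (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mu)
    count = 0
    total = 0
    for subset in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(subset)].sum() - mu) >= obs_dev - 1e-9:
            count += 1
    return count / total


def _vectorized_rank_sum_p(
    values: np.ndarray, in_cluster: np.ndarray, exact_limit: int = EXACT_GROUP_LIMIT
) -> np.ndarray:
    """Per-gene two-sided rank-sum p over a spots x genes matrix."""
    n_in = int(in_cluster.sum())
    n_out = int((~in_cluster).sum())
    if min(n_in, n_out) <= exact_limit and max(n_in, n_out) <= exact_limit:
        return np.array(
            [
                wilcoxon_rank_sum(values[in_cluster, j], values[~in_cluster, j], exact_limit)
                for j in range(values.shape[1])
            ]
        )
    res = scipy.stats.mannwhitneyu(
        values[in_cluster],
        values[~in_cluster],
        method="asymptotic",
        use_continuity=True,
        axis=0,
    )
    return np.asarray(res.pvalue, dtype=float)


def cluster_marker_stats(
    norm: NormalizedMatrix,
    labels: ClusterLabels,
    cluster: int,
    pseudocount: float = 1.0,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """One-vs-rest marker statistics for every gene in one cluster.

    Returns a gene-indexed frame with p_val, avg_log2FC, pct.1, pct.2
    and p_val_adj.  avg_log2FC compares de-logged means with a
    pseudocount:  log2((mean expm1 in + c) / (mean expm1 out + c)).
    """
    barcode_to_label = dict(zip(labels.barcodes, labels.labels))
    try:
        spot_labels = np.array([barcode_to_label[b] for b in norm.barcodes])
    except KeyError as exc:
        raise ValueError(f"spot without cluster label: {exc.args[0]}") from exc
    if cluster not in set(labels.labels.tolist()):
        raise ValueError(f"unknown cluster id: {cluster}")
    in_cluster = spot_labels == cluster
    if not in_cluster.any():
        raise ValueError(f"cluster {cluster} has no spots in this species")
    if in_cluster.all():
        raise ValueError(f"cluster {cluster} has an empty complement")

    values = norm.values
    p_val = _vectorized_rank_sum_p(values, in_cluster)

    expm1 = np.expm1(values)
    mean_in = expm1[in_cluster].mean(axis=0)
    mean_out = expm1[~in_cluster].mean(axis=0)
    avg_log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))

    pct_1 = (values[in_cluster] > 0).mean(axis=0)
    pct_2 = (values[~in_cluster] > 0).mean(axis=0)

    n_genes = values.shape[1]
    if adjust == "bonferroni":
        p_adj = np.minimum(p_val * n_genes, 1.0)
    elif adjust == "bh":
        p_adj = scipy.stats.false_discovery_control(p_val, method="bh")
    else:
        raise ValueError(f"unknown adjustment: {adjust}")

    return pd.DataFrame(
        {
            "p_val": p_val,
            "avg_log2FC": avg_log2fc,
            "pct.1": pct_1,
            "pct.2": pct_2,
            "p_val_adj": p_adj,
        },
        index=pd.Index(norm.gene_symbols, name="gene"),
    )


def tippett_minimum_p(p_values: list[float] | np.ndarray) -> float:
    """Minimum-p combination over k studies: 1 - (1 - min p)^k."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    combined = 1.0 - (1.0 - p.min()) ** p.size
    return float(np.clip(combined, P_FLOOR, 1.0))


def combine_conserved(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> pd.DataFrame:
    """Pair two species' per-gene stats and combine their p-values.

    Only genes tested in both species are kept.  Columns are prefixed
    ``A_`` / ``B_``; adds max_pval and minimump_p_val.
    """
    shared = stats_a.index.intersection(stats_b.index)
    a = stats_a.loc[shared].add_prefix("A_")
    b = stats_b.loc[shared].add_prefix("B_")
    out = pd.concat([a, b], axis=1)
    p_pair = out[["A_p_val", "B_p_val"]].to_numpy()
    out["max_pval"] = p_pair.max(axis=1)
    out["minimump_p_val"] = np.clip(
        1.0 - (1.0 - p_pair.min(axis=1)) ** 2, P_FLOOR, 1.0
    )
    return out


def rang_score(
    minimump_p_val: float | np.ndarray,
    pct_sum: float | np.ndarray,
    mean_log2fc: float | np.ndarray,
) -> float | np.ndarray:
    """rang = (-log2 minimump) * (pct.1 sum) * (mean log2FC)."""
    floored = np.maximum(minimump_p_val, P_FLOOR)
    return -np.log2(floored) * pct_sum * mean_log2fc


def filter_and_rank(
    records: pd.DataFrame,
    min_log2fc: float = 1.0,
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """Apply the both-species conservation filters and rank by ``rang``.

    Keeps genes with avg_log2FC strictly above ``min_log2fc`` and pct.1
    strictly above ``min_pct`` in both species; adds sum, sumLog and
    rang; sorts by rang descending with ties broken by gene symbol.
    """
    keep = (
        (records["A_avg_log2FC"] > min_log2fc)
        & (records["B_avg_log2FC"] > min_log2fc)
        & (records["A_pct.1"] > min_pct)
        & (records["B_pct.1"] > min_pct)
    )
    out = records.loc[keep].copy()
    out["sum"] = out["A_pct.1"] + out["B_pct.1"]
    out["sumLog"] = (out["A_avg_log2FC"] + out["B_avg_log2FC"]) / 2.0
    out["rang"] = rang_score(
        out["minimump_p_val"].to_numpy(),
        out["sum"].to_numpy(),
        out["sumLog"].to_numpy(),
    )
    out = out.sort_index().sort_values("rang", ascending=False, kind="stable")
    return out


def conserved_markers_for_cluster(
    norm_a: NormalizedMatrix,
    norm_b: NormalizedMatrix,
    labels: ClusterLabels,
    cluster: int,
    min_log2fc: float = 1.0,
    min_pct: float = 0.1,
    pseudocount: float = 1.0,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Full per-cluster pipeline: per-species DE -> combine -> filter/rank."""
    mask_a = np.isin(labels.barcodes, norm_a.barcodes)
    mask_b = np.isin(labels.barcodes, norm_b.barcodes)
    stats_a = cluster_marker_stats(
        norm_a, labels.subset(mask_a), cluster, pseudocount, adjust
    )
    stats_b = cluster_marker_stats(
        norm_b, labels.subset(mask_b), cluster, pseudocount, adjust
    )
    combined = combine_conserved(stats_a, stats_b)
    return filter_and_rank(combined, min_log2fc=min_log2fc, min_pct=min_pct)


def export_dotplot_table(
    ranked: pd.DataFrame,
    norms: dict[str, NormalizedMatrix],
    labels: ClusterLabels,
    top_n: int = 40,
) -> pd.DataFrame:
    """Plot-ready table: mean expression and detection % per gene/cluster/species."""
    genes = list(ranked.index[:top_n])
    rows = []
    for species, norm in norms.items():
        barcode_to_label = dict(zip(labels.barcodes, labels.labels))
        spot_labels = np.array(
            [barcode_to_label.get(b, -1) for b in norm.barcodes]
        )
        for cluster in labels.cluster_ids():
            in_cluster = spot_labels == cluster
            if not in_cluster.any():
                continue
            for gene in genes:
                if gene not in norm.gene_symbols:
                    continue
                col = norm.values[in_cluster, norm.gene_symbols.index(gene)]
                rows.append(
                    {
                        "gene": gene,
                        "cluster": labels.name_of(cluster),
                        "species": species,
                        "mean_expression": float(col.mean()),
                        "pct_detected": float((col > 0).mean() * 100.0),
                    }
                )
    columns = ["gene", "cluster", "species", "mean_expression", "pct_detected"]
    return pd.DataFrame(rows, columns=columns)
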