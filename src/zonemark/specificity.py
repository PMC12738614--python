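"""Signature-specificity statistics: module score, AUC, profile ρ, Δρ, permutation null.

Quantifies how specifically a cross-species gene signature marks one
cluster in the scored species: a per-spot module score (signature mean
minus bin-matched control mean), ROC/AUC of that score for the target
cluster, Spearman correlations between a reference log2FC profile and
every cluster's profile over the signature genes, the specificity margin
Δρ (target ρ minus the next best), and an empirical p-value from random
same-sized gene sets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from zonemark.markers import cluster_marker_stats
from zonemark.preprocess import ClusterLabels, NormalizedMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100
DEFAULT_SET_SIZE = 18
DEFAULT_N_PERM = 5000


@dataclass
class SignatureScore:
    """Per-spot module score for a gene signature."""

    scores: np.ndarray
    barcodes: list[str]
    signature: list[str]
    n_bins: int = DEFAULT_N_BINS
    n_ctrl: int = DEFAULT_N_CTRL
    seed: int = 0


@dataclass
class SpecificityReport:
    """Everything the conservation-specificity analysis produces."""

    median_scores: dict[str, float]
    auc: float
    rho: dict[str, float]
    target: str
    delta_rho: float
    observed_rho: float
    perm_rhos: np.ndarray
    empirical_p: float
    set_size: int = DEFAULT_SET_SIZE
    signature: list[str] = field(default_factory=list)
    background_size: int = 0

    def to_dict(self) -> dict:
        return {
            "median_scores": self.median_scores,
            "auc": self.auc,
            "rho": self.rho,
            "target": self.target,
            "delta_rho": self.delta_rho,
            "observed_rho": self.observed_rho,
            "empirical_p": self.empirical_p,
            "n_perm": int(len(self.perm_rhos)),
            "set_size": self.set_size,
            "signature": self.signature,
            "background_size": self.background_size,
        }

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        perm_path = path.with_suffix(".perm_rhos.tsv")
        pd.Series(self.perm_rhos, name="perm_rho").to_csv(
            perm_path, sep="\t", index=False
        )


def score_module(
    norm: NormalizedMatrix,
    signature: list[str],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> SignatureScore:
    """Per-spot gene-set score against bin-matched random controls.

    Genes are ranked by mean expression over all spots and cut into
    ``n_bins`` equal-frequency bins.  For each signature gene, ``n_ctrl``
    control genes are drawn uniformly with replacement from its bin
    (signature genes themselves are excluded from the control pool so
    the score is exactly linear in any shift of the signature genes that
    preserves the mean-expression ranking).
    score(spot) = mean over signature genes - mean over pooled controls.
    """
    present = [g for g in signature if g in norm.gene_symbols]
    dropped = set(signature) - set(present)
    if dropped:
        warnings.warn(
            f"{len(dropped)} signature genes absent from panel: {sorted(dropped)[:5]}...",
            stacklevel=2,
        )
    if not present:
        raise ValueError("no signature genes present in the matrix")

    values = norm.values
    gene_means = values.mean(axis=0)
    n_genes = len(norm.gene_symbols)
    order = np.argsort(gene_means, kind="stable")
    # equal-frequency bins over the mean-expression ranking
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // n_genes, n_bins - 1
    )

    sig_idx = norm.gene_index(present)
    sig_set = set(sig_idx.tolist())
    rng = np.random.default_rng(seed)
    control_idx: list[int] = []
    for g in sig_idx:
        bin_members = np.flatnonzero(bin_of == bin_of[g])
        pool = bin_members[~np.isin(bin_members, list(sig_set))]
        if pool.size == 0:
            warnings.warn(
                "control bin contains only signature genes; using full bin",
                stacklevel=2,
            )
            pool = bin_members
        control_idx.extend(rng.choice(pool, size=n_ctrl, replace=True).tolist())

    sig_score = values[:, sig_idx].mean(axis=1)
    ctrl_score = values[:, control_idx].mean(axis=1)
    return SignatureScore(
        scores=sig_score - ctrl_score,
        barcodes=list(norm.barcodes),
        signature=present,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def roc_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic: (concordant + ties/2) / (n+ * n-)."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be nonempty")
    ranks = scipy.stats.rankdata(scores)
    rank_sum_pos = ranks[positive].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def log2fc_profiles(
    norm: NormalizedMatrix,
    labels: ClusterLabels,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest avg_log2FC per gene (rows) per cluster (columns).

    Shares the exact code path of the marker statistics, so profile
    values equal ``cluster_marker_stats`` output.
    """
    barcode_set = set(norm.barcodes)
    mask = np.array([b in barcode_set for b in labels.barcodes])
    sub = labels.subset(mask)
    clusters = sub.cluster_ids()
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for log2FC profiles")
    profiles = {}
    for cluster in clusters:
        stats = cluster_marker_stats(norm, sub, cluster, pseudocount=pseudocount)
        profiles[labels.name_of(cluster)] = stats["avg_log2FC"]
    return pd.DataFrame(profiles)


def profile_correlation(
    ref_profile: pd.Series,
    cluster_profile: pd.Series,
    signature: list[str],
) -> float:
    """Spearman ρ between two log2FC profiles over the signature genes.

    Genes missing from either profile are dropped pairwise (with a
    warning); at least 3 shared genes are required.
    """
    pairs = pd.DataFrame({"ref": ref_profile, "other": cluster_profile}).reindex(
        signature
    )
    complete = pairs.dropna()
    if len(complete) < len(signature):
        warnings.warn(
            f"{len(signature) - len(complete)} signature genes missing from a profile",
            stacklevel=2,
        )
    if len(complete) < 3:
        raise ValueError("fewer than 3 signature genes shared between profiles")
    rho = scipy.stats.spearmanr(complete["ref"], complete["other"]).statistic
    return float(rho)


def specificity_margin(rho: dict[str, float], target: str) -> float:
    """Δρ = ρ(target) - max over non-target clusters of ρ."""
    if target not in rho:
        raise KeyError(f"target cluster {target!r} not in correlation map")
    others = [v for k, v in rho.items() if k != target]
    if not others:
        raise ValueError("need at least 2 clusters for a specificity margin")
    return float(rho[target] - max(others))


def empirical_p_value(
    perm_stats: np.ndarray, observed: float, plus_one: bool = False
) -> float:
    """Proportion of permuted statistics at or above the observed value.

    Default is the plain k/N proportion; ``plus_one`` switches to the
    (k+1)/(N+1) estimator.
    """
    perm_stats = np.asarray(perm_stats, dtype=float)
    if perm_stats.size == 0:
        raise ValueError("empty permutation vector")
    k = int((perm_stats >= observed).sum())
    if plus_one:
        return (k + 1) / (perm_stats.size + 1)
    return k / perm_stats.size


def permutation_test(
    ref_profile: pd.Series,
    target_profile: pd.Series,
    observed_rho: float,
    background: list[str],
    set_size: int = DEFAULT_SET_SIZE,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    plus_one: bool = False,
) -> tuple[np.ndarray, float]:
    """Null distribution of ρ over random same-sized gene sets.

    Each iteration samples ``set_size`` genes without replacement from
    ``background`` and recomputes Spearman ρ between the two profiles
    over that set.  Returns the permuted ρ vector and the empirical p
    (proportion of permuted values >= observed).
    """
    background = [
        g for g in background if g in ref_profile.index and g in target_profile.index
    ]
    if len(background) < set_size:
        raise ValueError(
            f"background ({len(background)} genes) smaller than set size {set_size}"
        )
    ref = ref_profile.reindex(background).to_numpy(dtype=float)
    tgt = target_profile.reindex(background).to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    n_bg = len(background)
    perm_rhos = np.empty(n_perm)
    for it in range(n_perm):
        idx = rng.choice(n_bg, size=set_size, replace=False)
        r1 = scipy.stats.rankdata(ref[idx])
        r2 = scipy.stats.rankdata(tgt[idx])
        r1 = r1 - r1.mean()
        r2 = r2 - r2.mean()
        denom = np.sqrt((r1 @ r1) * (r2 @ r2))
        perm_rhos[it] = (r1 @ r2) / denom if denom > 0 else 0.0
    return perm_rhos, empirical_p_value(perm_rhos, observed_rho, plus_one=plus_one)


def run_specificity(
    norm_ref: NormalizedMatrix,
    norm_scored: NormalizedMatrix,
    labels: ClusterLabels,
    signature: list[str],
    target: str,
    reference_cluster: str | None = None,
    background: list[str] | None = None,
    set_size: int = DEFAULT_SET_SIZE,
    n_perm: int = DEFAULT_N_PERM,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> SpecificityReport:
    """Full conservation-specificity analysis.

    ``norm_ref`` supplies the reference log2FC profile (the cluster named
    ``reference_cluster``, defaulting to ``target``); ``norm_scored`` is
    the species whose spots are scored and whose clusters are correlated
    against the reference.
    """
    reference_cluster = reference_cluster or target

    score = score_module(
        norm_scored, signature, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
    )
    barcode_to_label = dict(zip(labels.barcodes, labels.labels))
    spot_labels = np.array([barcode_to_label[b] for b in score.barcodes])
    name_of = {c: labels.name_of(c) for c in labels.cluster_ids()}

    median_scores = {
        name_of[c]: float(np.median(score.scores[spot_labels == c]))
        for c in sorted(set(spot_labels.tolist()))
    }
    target_ids = [c for c, n in name_of.items() if n == target]
    if not target_ids:
        raise KeyError(f"target cluster {target!r} not found")
    positive = np.isin(spot_labels, target_ids)
    auc = roc_auc(score.scores, positive)

    profiles_ref = log2fc_profiles(norm_ref, labels, pseudocount=pseudocount)
    profiles_scored = log2fc_profiles(norm_scored, labels, pseudocount=pseudocount)
    if reference_cluster not in profiles_ref.columns:
        raise KeyError(f"reference cluster {reference_cluster!r} has no profile")
    ref_profile = profiles_ref[reference_cluster]

    rho = {
        cluster: profile_correlation(ref_profile, profiles_scored[cluster], signature)
        for cluster in profiles_scored.columns
        if cluster in profiles_scored
    }
    delta = specificity_margin(rho, target)

    if background is None:
        background = [
            g
            for g in norm_scored.gene_symbols
            if g in profiles_ref.index and g in profiles_scored.index
        ]
    perm_rhos, emp_p = permutation_test(
        ref_profile,
        profiles_scored[target],
        rho[target],
        background=background,
        set_size=set_size,
        n_perm=n_perm,
        seed=seed,
    )
    logger.info(
        "specificity: AUC=%.3f rho(target)=%.3f delta_rho=%.3f empirical_p=%.2e",
        auc,
        rho[target],
        delta,
        emp_p,
    )
    return SpecificityReport(
        median_scores=median_scores,
        auc=auc,
        rho=rho,
        target=target,
        delta_rho=delta,
        observed_rho=rho[target],
        perm_rhos=perm_rhos,
        empirical_p=emp_p,
        set_size=set_size,
        signature=list(signature),
        background_size=len(background),
    )
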