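import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from zonemark import simulate, specificity
from zonemark.preprocess import NormalizedMatrix, labels_from_zones
from zonemark.specificity import (
    empirical_p_value,
    log2fc_profiles,
    permutation_test,
    profile_correlation,
    roc_auc,
    run_specificity,
    score_module,
    specificity_margin,
)


def make_norm(values, genes=None, prefix="BC"):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values=values,
        barcodes=[f"{prefix}{i:04d}" for i in range(values.shape[0])],
        gene_symbols=genes or [f"G{j}" for j in range(values.shape[1])],
    )


class TestModuleScore:
    def test_constant_expression_scores_zero(self):
        values = np.full((20, 40), 2.5)
        score = score_module(make_norm(values), ["G0", "G1"], n_bins=4, seed=0)
        np.testing.assert_allclose(score.scores, 0.0, atol=1e-12)

    def test_exactly_linear_in_signature_shift(self, rng):
        # the shift must preserve the mean-expression ranking (signature
        # genes stay in their bins); controls are then untouched and the
        # score moves by exactly c
        values = rng.random((30, 60)) + 1.0
        signature = ["G5", "G17", "G33"]
        for g in signature:
            values[:, int(g[1:])] += 5.0  # top-ranked means
        base = score_module(make_norm(values), signature, n_bins=5, seed=3)
        shifted_values = values.copy()
        for g in signature:
            shifted_values[:, int(g[1:])] += 0.7
        shifted = score_module(make_norm(shifted_values), signature, n_bins=5, seed=3)
        np.testing.assert_allclose(shifted.scores - base.scores, 0.7, atol=1e-9)

    def test_deterministic_for_fixed_seed(self, rng):
        values = rng.random((25, 50))
        a = score_module(make_norm(values), ["G1", "G2"], seed=9)
        b = score_module(make_norm(values), ["G1", "G2"], seed=9)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_missing_signature_genes_warn_then_error(self, rng):
        values = rng.random((10, 5))
        with pytest.warns(UserWarning, match="absent"):
            score_module(make_norm(values), ["G0", "NOPE"], seed=0)
        with pytest.raises(ValueError, match="no signature genes"):
            score_module(make_norm(values), ["NOPE"], seed=0)

    def test_planted_signature_scores_highest_in_home_zone(
        self, default_bundle, default_norms, truth_labels
    ):
        _, norm_b = default_norms
        score = score_module(norm_b, default_bundle.truth.signature, seed=0)
        label_of = dict(zip(truth_labels.barcodes, truth_labels.labels))
        spot_labels = np.array([label_of[b] for b in score.barcodes])
        medians = {
            truth_labels.name_of(c): np.median(score.scores[spot_labels == c])
            for c in sorted(set(spot_labels.tolist()))
        }
        assert max(medians, key=medians.get) == "INNER"


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc(np.array([1, 2, 3, 10, 11]), np.array(
            [False, False, False, True, True]
        )) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc(np.ones(10), np.arange(10) < 4) == 0.5

    def test_hand_counted_example(self):
        # scores (.9,.8,.7,.6), labels (+,-,+,-): concordant pairs 3 of 4
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([True, False, True, False])
        assert roc_auc(scores, labels) == pytest.approx(0.75)

    def test_one_class_empty_errors(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([True, True]))

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            scores = rng.integers(0, 10, n).astype(float)  # force ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            pos = scores[labels]
            neg = scores[~labels]
            pairs = [(p > q) + 0.5 * (p == q) for p in pos for q in neg]
            assert roc_auc(scores, labels) == pytest.approx(np.mean(pairs))

    def test_complement_property(self, rng):
        scores = rng.normal(size=40)  # tie-free
        labels = rng.random(40) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)


class TestProfiles:
    def test_identical_clusters_give_zero_log2fc(self, rng):
        block = rng.random((40, 12))
        values = np.vstack([block, block])
        norm = make_norm(values)
        labels = labels_from_zones(
            {b: ("C1" if i < 40 else "C2") for i, b in enumerate(norm.barcodes)},
            norm.barcodes,
        )
        profiles = log2fc_profiles(norm, labels)
        assert profiles.abs().to_numpy().max() < 1e-9

    def test_profiles_equal_marker_stats(self, default_norms, truth_labels):
        from zonemark.markers import cluster_marker_stats

        norm_a, _ = default_norms
        profiles = log2fc_profiles(norm_a, truth_labels)
        mask = np.isin(truth_labels.barcodes, norm_a.barcodes)
        sub = truth_labels.subset(mask)
        cluster = sub.cluster_ids()[0]
        stats = cluster_marker_stats(norm_a, sub, cluster)
        np.testing.assert_array_equal(
            profiles[truth_labels.name_of(cluster)].to_numpy(),
            stats["avg_log2FC"].to_numpy(),
        )

    def test_planted_marker_has_high_profile_value(
        self, default_bundle, default_norms, truth_labels
    ):
        norm_a, _ = default_norms
        profiles = log2fc_profiles(norm_a, truth_labels)
        genes = default_bundle.truth.genes
        inner = genes[(genes["home_zone"] == "INNER") & (genes["fold_a"] > 1)]
        present = [g for g in inner["symbol_a"] if g in profiles.index]
        assert (profiles.loc[present, "INNER"] > 1).mean() > 0.9


class TestCorrelationAndMargin:
    def test_self_correlation_is_one(self):
        profile = pd.Series([0.3, 1.2, -0.5, 2.0, 0.0],
                            index=[f"G{j}" for j in range(5)])
        assert profile_correlation(
            profile, profile, list(profile.index)
        ) == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        idx = [f"G{j}" for j in range(5)]
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=idx)
        assert profile_correlation(a, -a, idx) == pytest.approx(-1.0)

    def test_hand_ranked_toy(self):
        # (1,2,3,4,5) vs (3,1,2,5,4): rho = 0.6 by direct rank computation
        idx = [f"G{j}" for j in range(5)]
        a = pd.Series([1, 2, 3, 4, 5], index=idx, dtype=float)
        b = pd.Series([3, 1, 2, 5, 4], index=idx, dtype=float)
        assert profile_correlation(a, b, idx) == pytest.approx(0.6)

    def test_missing_genes_dropped_pairwise(self):
        idx = [f"G{j}" for j in range(6)]
        a = pd.Series(np.arange(6.0), index=idx)
        b = a.drop("G3")
        with pytest.warns(UserWarning, match="missing"):
            rho = profile_correlation(a, b, idx)
        assert rho == pytest.approx(1.0)

    def test_too_few_genes_errors(self):
        a = pd.Series([1.0, 2.0], index=["G0", "G1"])
        with pytest.raises(ValueError, match="fewer than 3"):
            profile_correlation(a, a, ["G0", "G1"])

    def test_printed_correlation_map_margin(self):
        # per-cluster correlations 0.8 / 0.4 / 0.4 / 0.4 / -0.8, target best
        rho = {"BAT": 0.8, "ZF": 0.4, "ZG": 0.4, "medulla": 0.4, "CT/WAT": -0.8}
        assert specificity_margin(rho, "BAT") == pytest.approx(0.4)

    def test_equal_correlations_give_zero_margin(self):
        assert specificity_margin({"A": 0.5, "B": 0.5}, "A") == 0.0

    def test_non_maximal_target_gives_negative_margin(self):
        assert specificity_margin({"A": 0.1, "B": 0.5}, "A") == pytest.approx(-0.4)

    def test_singleton_map_errors(self):
        with pytest.raises(ValueError):
            specificity_margin({"A": 0.5}, "A")


class TestPermutation:
    def test_three_exceedances_in_5000(self):
        perm = np.concatenate([np.full(4997, -0.5), np.full(3, 0.95)])
        assert empirical_p_value(perm, 0.9) == pytest.approx(6e-4)

    def test_observed_below_all_gives_one(self):
        perm = np.linspace(0.1, 0.9, 100)
        assert empirical_p_value(perm, 0.0) == 1.0

    def test_plus_one_estimator(self):
        perm = np.zeros(99)
        assert empirical_p_value(perm, 1.0, plus_one=True) == pytest.approx(1 / 100)

    @given(st.floats(min_value=-1.0, max_value=1.0),
           st.floats(min_value=-1.0, max_value=1.0))
    @settings(deadline=None)
    def test_monotone_in_observed(self, obs1, obs2):
        perm = np.linspace(-1, 1, 50)
        lo, hi = sorted([obs1, obs2])
        assert empirical_p_value(perm, lo) >= empirical_p_value(perm, hi)

    def test_sampling_without_replacement_and_determinism(self, rng):
        idx = [f"G{j}" for j in range(40)]
        ref = pd.Series(rng.normal(size=40), index=idx)
        tgt = pd.Series(rng.normal(size=40), index=idx)
        perm1, p1 = permutation_test(ref, tgt, 0.5, background=idx,
                                     set_size=10, n_perm=200, seed=4)
        perm2, p2 = permutation_test(ref, tgt, 0.5, background=idx,
                                     set_size=10, n_perm=200, seed=4)
        np.testing.assert_array_equal(perm1, perm2)
        assert p1 == p2
        assert np.isfinite(perm1).all()
        assert (np.abs(perm1) <= 1.0 + 1e-12).all()

    def test_background_too_small_errors(self):
        idx = ["G0", "G1"]
        profile = pd.Series([1.0, 2.0], index=idx)
        with pytest.raises(ValueError, match="background"):
            permutation_test(profile, profile, 0.5, background=idx,
                             set_size=5, n_perm=10)

    def test_permuted_rho_matches_scipy_spearman(self, rng):
        idx = [f"G{j}" for j in range(30)]
        ref = pd.Series(rng.integers(0, 5, 30).astype(float), index=idx)
        tgt = pd.Series(rng.integers(0, 5, 30).astype(float), index=idx)
        perm, _ = permutation_test(ref, tgt, 0.9, background=idx,
                                   set_size=12, n_perm=20, seed=1)
        # same seed, same draws: recompute each iteration with scipy
        check_rng = np.random.default_rng(1)
        for value in perm:
            subset = check_rng.choice(30, size=12, replace=False)
            expected = scipy.stats.spearmanr(
                ref.iloc[subset], tgt.iloc[subset]
            ).statistic
            assert value == pytest.approx(expected, rel=1e-9)


class TestEndToEnd:
    def test_planted_signature_report(self, default_bundle, default_norms, truth_labels):
        norm_a, norm_b = default_norms
        report = run_specificity(
            norm_ref=norm_a,
            norm_scored=norm_b,
            labels=truth_labels,
            signature=default_bundle.truth.signature,
            target="INNER",
            n_perm=1000,
            seed=0,
        )
        assert max(report.median_scores, key=report.median_scores.get) == "INNER"
        assert report.auc >= 0.9
        assert report.delta_rho > 0
        assert report.empirical_p <= 0.01
        assert report.rho["INNER"] == report.observed_rho

    def test_report_round_trips_to_json(self, tmp_path, default_bundle,
                                        default_norms, truth_labels):
        import json

        norm_a, norm_b = default_norms
        report = run_specificity(
            norm_ref=norm_a,
            norm_scored=norm_b,
            labels=truth_labels,
            signature=default_bundle.truth.signature,
            target="INNER",
            n_perm=50,
            seed=0,
        )
        report.write(tmp_path / "spec.json")
        loaded = json.loads((tmp_path / "spec.json").read_text())
        assert loaded["auc"] == report.auc
        assert loaded["n_perm"] == 50
        perm = pd.read_csv(tmp_path / "spec.perm_rhos.tsv", sep="\t")
        assert len(perm) == 50


def test_null_calibration_uniform():
    """Empirical p under the no-shared-signature null is ~ Uniform(0,1)."""
    bundle = simulate.generate_dataset(simulate.null_config(seed=5))
    from zonemark import io, preprocess

    matrix_a = io.filter_genes_min_fraction(
        io.filter_spots_in_tissue(bundle.matrix_a)
    )
    matrix_b = io.filter_genes_min_fraction(
        io.filter_spots_in_tissue(bundle.matrix_b)
    )
    matrix_b = io.apply_ortholog_map(matrix_b, bundle.ortholog_map)
    norm_a = preprocess.log_normalize(matrix_a)
    norm_b = preprocess.log_normalize(matrix_b)
    zones = {}
    for layout in bundle.truth.spots.values():
        in_tissue = layout[layout["in_tissue"] == 1]
        zones.update(dict(zip(in_tissue["barcode"], in_tissue["zone"])))
    labels = labels_from_zones(
        zones, list(norm_a.barcodes) + list(norm_b.barcodes)
    )
    profiles_a = log2fc_profiles(norm_a, labels)
    profiles_b = log2fc_profiles(norm_b, labels)
    background = sorted(set(profiles_a.index) & set(profiles_b.index))

    master = np.random.default_rng(2024)
    p_values = []
    for repeat in range(200):
        sig_rng = np.random.default_rng(master.integers(2**63))
        signature = list(sig_rng.choice(background, size=18, replace=False))
        observed = profile_correlation(
            profiles_a["INNER"], profiles_b["INNER"], signature
        )
        _, p = permutation_test(
            profiles_a["INNER"],
            profiles_b["INNER"],
            observed,
            background=background,
            set_size=18,
            n_perm=500,
            seed=int(master.integers(2**31)),
        )
        p_values.append(p)
    ks = scipy.stats.kstest(p_values, "uniform")
    assert ks.pvalue > 0.01
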