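"""Rank-sum and permutation-t differential-abundance tests, multiplicity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from annocompare import fixtures
from annocompare.stats import (
    bonferroni,
    differential_abundance,
    group_medians,
    metastats,
    pairwise_distance_comparison,
    wilcoxon_rank_sum,
)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_fully_separated_triples_exact(self):
        # 2 of the C(6,3)=20 equally likely rank assignments are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_enumeration_matches_combinatorics(self):
        # independently enumerate all rank splits for a small example
        a, b = [1.2, 3.4, 2.2], [5.0, 0.1, 4.4]
        observed = sum(sorted(a + b).index(v) + 1 for v in a)
        pooled = sorted(a + b)
        stats = []
        for combo in itertools.combinations(range(1, 7), 3):
            stats.append(sum(combo))
        stats = np.array(stats)
        lower = np.mean(stats <= observed)
        upper = np.mean(stats >= observed)
        expected = min(1.0, 2 * min(lower, upper))
        assert wilcoxon_rank_sum(a, b, method="exact") == pytest.approx(expected)

    def test_exact_and_normal_paths_agree_for_moderate_n(self, rng):
        for _ in range(20):
            a = rng.normal(size=10)
            b = rng.normal(size=10) + rng.uniform(-1, 1)
            exact = wilcoxon_rank_sum(a, b, method="exact")
            approx = wilcoxon_rank_sum(a, b, method="asymptotic")
            assert abs(exact - approx) < 0.02

    def test_two_sided_is_twice_smaller_one_sided_without_ties(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        one_sided = min(
            wilcoxon_rank_sum(a, b, "less", method="exact"),
            wilcoxon_rank_sum(a, b, "greater", method="exact"),
        )
        two_sided = wilcoxon_rank_sum(a, b, "two-sided", method="exact")
        assert two_sided == pytest.approx(min(1.0, 2 * one_sided))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBonferroni:
    def test_single_test_is_identity(self):
        assert bonferroni([0.3]) == pytest.approx([0.3])

    def test_clamped_at_one(self):
        assert bonferroni([0.3, 0.6, 0.9, 0.2]).max() == 1.0

    def test_scales_by_family_size(self):
        adjusted = bonferroni([0.004] + [0.5] * 9)
        assert adjusted[0] == pytest.approx(0.04)

    def test_never_decreases_and_preserves_order(self, rng):
        p = rng.uniform(size=20)
        adjusted = bonferroni(p)
        assert (adjusted >= p).all()
        # weakly order-preserving (clamping at 1 may introduce ties)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adjusted[order]) >= 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])


class TestGroupMedians:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["f1"])

    def test_identical_groups_have_unit_ratio(self):
        a = self.frame([[0.2], [0.3], [0.4]])
        out = group_medians(a, a.copy())
        assert out.loc["f1", "median_ratio"] == pytest.approx(1.0)

    def test_constant_groups_ratio_two(self):
        a = self.frame([[0.2]] * 4)
        b = self.frame([[0.1]] * 4)
        out = group_medians(a, b)
        assert out.loc["f1", "median_pct_a"] == pytest.approx(20.0)
        assert out.loc["f1", "median_pct_b"] == pytest.approx(10.0)
        assert out.loc["f1", "median_ratio"] == pytest.approx(2.0)

    def test_even_n_uses_mean_of_middle_two(self, rng):
        values = rng.uniform(size=6)
        a = self.frame([[v] for v in values])
        ordered = np.sort(values)
        expected = (ordered[2] + ordered[3]) / 2 * 100
        out = group_medians(a, a.copy())
        assert out.loc["f1", "median_pct_a"] == pytest.approx(expected)

    def test_zero_b_median_reports_infinity(self):
        a = self.frame([[0.2]] * 3)
        b = self.frame([[0.0]] * 3)
        out = group_medians(a, b)
        assert np.isinf(out.loc["f1", "median_ratio"])


def count_matrices(rng, n_a=8, n_b=8, m=30, shift=None):
    counts = rng.poisson(rng.lognormal(3.0, 0.6, size=(n_a + n_b, m))).astype(float)
    columns = [f"f{i}" for i in range(m)]
    if shift is not None:
        feature, fold = shift
        counts[:n_a, columns.index(feature)] *= fold
    return (
        pd.DataFrame(counts[:n_a], columns=columns),
        pd.DataFrame(counts[n_a:], columns=columns),
    )


class TestMetastats:
    def test_permutation_p_has_add_one_floor(self, rng):
        a, b = count_matrices(rng, shift=("f0", 40.0))
        result = metastats(a, b, permutations=50, seed=0)
        assert (result["p_value"] >= 1.0 / 51.0).all()
        assert result.loc["f0", "p_value"] == pytest.approx(1.0 / 51.0)

    def test_reproducible_given_seed(self, rng):
        a, b = count_matrices(rng)
        first = metastats(a, b, permutations=200, seed=42)
        second = metastats(a, b, permutations=200, seed=42)
        pd.testing.assert_frame_equal(first, second)

    def test_invariant_to_sample_order_within_groups(self, rng):
        a, b = count_matrices(rng)
        shuffled = a.sample(frac=1.0, random_state=3)
        first = metastats(a, b, permutations=200, seed=7)
        second = metastats(shuffled, b, permutations=200, seed=7)
        assert np.allclose(first["p_value"], second["p_value"])

    def test_zero_variance_everywhere_gives_p_one(self):
        a = pd.DataFrame({"f1": [2.0] * 4, "f2": [6.0] * 4})
        b = pd.DataFrame({"f1": [1.0] * 4, "f2": [3.0] * 4})
        # relative abundances are constant 0.25/0.75 in both groups
        result = metastats(a, b, permutations=100, seed=0)
        assert (result["p_value"] == 1.0).all()

    def test_sparse_features_use_fisher_branch(self, rng):
        a, b = count_matrices(rng, m=5)
        a["rare"] = [1.0, 0, 0, 0, 0, 0, 0, 0]
        b["rare"] = [0.0] * 8
        result = metastats(a, b, permutations=100, seed=0, sparse_threshold=8)
        assert result.loc["rare", "test"] == "fisher"
        assert 0.0 <= result.loc["rare", "p_value"] <= 1.0
        assert (result.drop("rare")["test"] == "t-permutation").all()

    def test_ci_brackets_the_mean_difference(self, rng):
        a, b = count_matrices(rng)
        result = metastats(a, b, permutations=50, seed=0)
        t_rows = result[result["test"] == "t-permutation"]
        diff = t_rows["mean_a"] - t_rows["mean_b"]
        assert (t_rows["ci_lower"] <= diff + 1e-12).all()
        assert (diff <= t_rows["ci_upper"] + 1e-12).all()

    def test_single_sample_group_rejected(self, rng):
        a, b = count_matrices(rng, n_a=1)
        with pytest.raises(ValueError):
            metastats(a, b, permutations=10, seed=0)


class TestDifferentialAbundance:
    def test_planted_fold_change_is_flagged_by_both_tests(self):
        spec = fixtures.FixtureSpec(
            seed=21,
            n_datasets=20,
            n_records=300,
            n_habitats=2,
            shared_centroid=True,
            concentration=200.0,
            planted_effects=(fixtures.PlantedEffect("K00003", 2.0, 0, baseline=0.05),),
        )
        datasets, truth = fixtures.synth_datasets(spec)
        group_a = [d for d in datasets if truth.habitat[d.library_id] == 0]
        group_b = [d for d in datasets if truth.habitat[d.library_id] == 1]
        wilcoxon = differential_abundance(group_a, group_b, "ko", test="wilcoxon")
        permutation = differential_abundance(
            group_a, group_b, "ko", test="metastats", permutations=500, seed=5
        )
        assert wilcoxon.loc["K00003", "adj_p_value"] < 0.05
        assert permutation.loc["K00003", "adj_p_value"] < 0.05

    def test_unknown_test_rejected(self, habitat_family):
        datasets, _ = habitat_family
        with pytest.raises(ValueError):
            differential_abundance(datasets[:3], datasets[3:], "ko", test="anova")


class TestPairwiseDistanceComparison:
    def test_identical_distributions_are_not_significant(self, rng):
        within = rng.uniform(0.2, 0.8, size=40)
        between = rng.uniform(0.2, 0.8, size=40)
        p = pairwise_distance_comparison(within, between)
        assert 0.05 < p < 0.95

    def test_shifted_within_distances_are_significant(self, rng):
        between = rng.uniform(0.4, 0.9, size=40)
        within = between[:20] - 0.3
        assert pairwise_distance_comparison(within, between) < 1e-4

    def test_single_pair_each_matches_enumeration(self):
        # with one distance per side and within < between, the one-sided
        # rank-sum p is 1/2 (one of the two equally likely orderings)
        assert pairwise_distance_comparison([0.1], [0.5]) == pytest.approx(0.5)
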