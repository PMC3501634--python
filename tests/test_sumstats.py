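"""Diversity statistics, permutation tests, Holm correction, and the
structure screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from msatdemog.coalescent import ConstantDemography, simulate_dataset
from msatdemog.genotypes import Locus
from msatdemog.mutation import MutationModel
from msatdemog.sumstats import (delta_mu2, delta_mu2_nj, effective_alleles,
                                fis, heterozygosities, hwe_gtest, ld_gtest,
                                locus_summaries, rst_screen,
                                sequential_bonferroni)

from conftest import make_matrix


class TestEffectiveAlleles:
    @pytest.mark.parametrize("freqs,expected", [
        ((0.5, 0.5), 2.0),
        ((1.0,), 1.0),
        ((0.7, 0.2, 0.1), 1 / 0.54),
        ((0.25,) * 4, 4.0),
    ])
    def test_known_values(self, freqs, expected):
        assert effective_alleles(freqs) == pytest.approx(expected, rel=1e-6)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            effective_alleles((0.5, 0.4))

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_allele_count(self, weights):
        p = np.array(weights) / np.sum(weights)
        ne = effective_alleles(p)
        assert 1.0 - 1e-9 <= ne <= len(p) + 1e-9


class TestHeterozygosities:
    def test_hand_example(self):
        g = make_matrix([[(10, 12)], [(10, 10)]])
        ho, he = heterozygosities(g, "L1")
        assert ho == pytest.approx(0.5)
        assert he == pytest.approx((4 / 3) * (1 - 0.625))

    def test_monomorphic_zero(self):
        g = make_matrix([[(10, 10)], [(10, 10)]])
        assert heterozygosities(g, "L1") == (0.0, 0.0)

    def test_invariant_to_relabeling(self):
        a = make_matrix([[(10, 12)], [(12, 14)], [(10, 10)]])
        b = make_matrix([[(20, 30)], [(30, 31)], [(20, 20)]])
        assert heterozygosities(a, "L1") == pytest.approx(
            heterozygosities(b, "L1"))


class TestHweGtest:
    def test_exact_hwe_counts_give_p_near_one(self, rng):
        calls = ([[(10, 10)]] * 25 + [[(10, 12)]] * 50 + [[(12, 12)]] * 25)
        p = hwe_gtest(make_matrix(calls), "L1", n_perm=400, rng=rng)
        assert p > 0.5

    def test_all_heterozygotes_rejected(self, rng):
        calls = [[(10, 12)]] * 50
        p = hwe_gtest(make_matrix(calls), "L1", n_perm=10000, rng=rng)
        assert p < 0.01

    def test_refuses_tiny_permutation_count(self, rng):
        with pytest.raises(ValueError):
            hwe_gtest(make_matrix([[(10, 12)]] * 4), "L1", n_perm=50, rng=rng)

    def test_p_uniform_under_null(self, rng):
        loci = [(Locus("L1", repeat_min=1, repeat_max=35),
                 MutationModel.from_name("EU1"))]
        ps = []
        for _ in range(50):
            g = simulate_dataset(15, loci, ConstantDemography(2.0), rng)
            if np.unique(g.gene_copies("L1")).size < 2:
                continue
            ps.append(hwe_gtest(g, "L1", n_perm=200, rng=rng))
        # permutation p-values are discrete/conservative; coarse KS guard
        assert kstest(ps, "uniform").pvalue > 0.001


class TestFis:
    def test_balanced_sample_near_zero(self, rng):
        calls = ([[(10, 10)]] * 25 + [[(10, 12)]] * 50 + [[(12, 12)]] * 25)
        per_locus, weighted, _ = fis(make_matrix(calls), n_rand=0, n_boot=0,
                                     rng=rng)
        assert abs(per_locus["L1"]) < 0.02
        assert abs(weighted) < 0.02

    def test_all_homozygotes_near_one(self, rng):
        calls = [[(10, 10)]] * 25 + [[(12, 12)]] * 25
        per_locus, _, _ = fis(make_matrix(calls), n_rand=0, n_boot=0, rng=rng)
        assert per_locus["L1"] == pytest.approx(1.0, abs=1e-9)

    def test_all_heterozygotes_negative(self, rng):
        calls = [[(10, 12)]] * 30
        per_locus, _, _ = fis(make_matrix(calls), n_rand=0, n_boot=0, rng=rng)
        assert per_locus["L1"] < 0

    def test_bootstrap_ci_brackets_weighted_mean(self, rng):
        loci = [(Locus(f"L{j}", repeat_min=1, repeat_max=35),
                 MutationModel.from_name("EU1")) for j in range(5)]
        g = simulate_dataset(20, loci, ConstantDemography(2.0), rng)
        _, weighted, (lo, hi) = fis(g, n_rand=0, n_boot=400, rng=rng)
        assert lo <= hi
        assert lo - 0.2 <= weighted <= hi + 0.2

    def test_monomorphic_skipped_with_warning(self, rng):
        g = make_matrix([[(10, 10)], [(10, 10)]])
        with pytest.warns(UserWarning, match="monomorphic"):
            per_locus, _, _ = fis(g, n_rand=0, n_boot=0, rng=rng)
        assert per_locus == {}


class TestLdGtest:
    def test_locus_paired_with_itself_rejected(self, rng):
        calls = np.array([[(10, 12), (10, 12)],
                          [(10, 10), (10, 10)],
                          [(12, 12), (12, 12)]] * 8)
        p = ld_gtest(make_matrix(calls), "L1", "L2", n_perm=600, rng=rng)
        assert p < 0.01

    def test_independent_loci_rejection_rate(self, rng):
        loci = [(Locus(f"L{j}", repeat_min=1, repeat_max=35),
                 MutationModel.from_name("EU1")) for j in range(2)]
        rej = trials = 0
        for _ in range(40):
            g = simulate_dataset(15, loci, ConstantDemography(2.0), rng)
            try:
                p = ld_gtest(g, "L0", "L1", n_perm=200, rng=rng)
            except ValueError:
                continue
            trials += 1
            rej += p <= 0.05
        assert trials >= 25
        se = np.sqrt(0.05 * 0.95 / trials)
        assert rej / trials <= 0.05 + 3 * se

    def test_requires_shared_individuals(self, rng):
        from msatdemog.genotypes import MISSING
        calls = np.array([[(10, 12), (MISSING, MISSING)],
                          [(MISSING, MISSING), (20, 22)]])
        with pytest.raises(ValueError):
            ld_gtest(make_matrix(calls), "L1", "L2", n_perm=150, rng=rng)


class TestSequentialBonferroni:
    def test_all_rejected(self):
        flags = sequential_bonferroni([0.01, 0.02, 0.04], alpha=0.05)
        assert flags.all()

    def test_none_rejected(self):
        flags = sequential_bonferroni([0.04, 0.5, 0.9], alpha=0.05)
        assert not flags.any()

    def test_boundary_inclusive(self):
        assert sequential_bonferroni([0.05], alpha=0.05)[0]

    def test_empty(self):
        assert sequential_bonferroni([], alpha=0.05).size == 0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_holm_rejects_superset_of_bonferroni(self, pvals):
        m = len(pvals)
        holm = sequential_bonferroni(pvals, alpha=0.05)
        bonf = np.asarray(pvals) <= 0.05 / m
        assert (holm | ~bonf).all()  # bonf => holm


class TestRst:
    def test_fixed_groups_near_one(self, rng):
        calls = [[(10, 10)]] * 10 + [[(30, 30)]] * 10
        g = make_matrix(calls, groups=["a"] * 10 + ["b"] * 10)
        screen = rst_screen(g, n_perm=200, rng=rng)
        assert screen.rst_overall == pytest.approx(1.0, abs=0.05)
        assert screen.p_overall < 0.05

    def test_duplicated_groups_nonpositive(self, rng):
        base = [[(10, 12)], [(12, 14)], [(10, 10)], [(14, 14)], [(10, 14)]]
        g = make_matrix(base * 2, groups=["a"] * 5 + ["b"] * 5)
        screen = rst_screen(g, n_perm=100, rng=rng)
        assert screen.rst_overall <= 1e-9

    def test_negative_estimates_reported_and_4nm_undefined(self, rng):
        base = [[(10, 12)], [(12, 14)], [(10, 10)], [(14, 14)], [(10, 14)]]
        g = make_matrix(base * 2, groups=["a"] * 5 + ["b"] * 5)
        screen = rst_screen(g, n_perm=100, rng=rng)
        if screen.rst_overall <= 0:
            assert screen.four_nm is None

    def test_panmictic_rarely_significant(self, rng):
        loci = [(Locus(f"L{j}", repeat_min=1, repeat_max=35),
                 MutationModel.from_name("EU1")) for j in range(4)]
        ok = 0
        n_rep = 20
        for _ in range(n_rep):
            g = simulate_dataset(16, loci, ConstantDemography(3.0), rng,
                                 group_sizes={"a": 8, "b": 8}, migration=200.0)
            screen = rst_screen(g, n_perm=150, rng=rng)
            ok += screen.p_overall > 0.05
        assert ok >= int(0.9 * n_rep) - 1

    def test_small_group_excluded_with_warning(self, rng):
        calls = [[(10, 12)], [(12, 14)], [(10, 10)], [(14, 14)], [(10, 14)]]
        g = make_matrix(calls * 2, groups=["a"] * 5 + ["b"] * 4 + ["c"])
        with pytest.warns(UserWarning, match="excluded"):
            screen = rst_screen(g, n_perm=100, rng=rng)
        assert list(screen.pairwise_rst.index) == ["a", "b"]


class TestDeltaMu2:
    def test_identical_groups_zero(self):
        base = [[(10, 12)], [(12, 14)]]
        g = make_matrix(base * 2, groups=["a", "a", "b", "b"])
        d = delta_mu2(g)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_single_locus_mean_difference_squared(self):
        g = make_matrix([[(10, 10)], [(12, 12)]], groups=["a", "b"])
        assert delta_mu2(g).loc["a", "b"] == pytest.approx(4.0)

    def test_two_groups_distance_only(self):
        g = make_matrix([[(10, 10)], [(12, 12)]], groups=["a", "b"])
        d, newick, split = delta_mu2_nj(g)
        assert newick is None and split is None

    def test_deepest_split_separates_clusters(self):
        # two clusters of three groups each, strongly separated mean sizes
        rows, groups = [], []
        for gi, (name, base) in enumerate([
            ("a1", 10), ("a2", 11), ("a3", 10),
            ("b1", 28), ("b2", 29), ("b3", 28),
        ]):
            for _ in range(3):
                rows.append([(base, base + 1)])
                groups.append(name)
        g = make_matrix(rows, groups=groups)
        _, newick, split = delta_mu2_nj(g)
        assert newick
        sides = {frozenset(split[0]), frozenset(split[1])}
        assert frozenset({"a1", "a2", "a3"}) in sides


class TestLocusSummaries:
    def test_table_columns_and_bounds(self, rng):
        loci = [(Locus(f"L{j}", repeat_min=1, repeat_max=35),
                 MutationModel.from_name("PU2")) for j in range(4)]
        g = simulate_dataset(20, loci, ConstantDemography(4.0), rng)
        table = locus_summaries(g)
        assert list(table["name"]) == [l.name for l in g.loci]
        assert (table["n_e"] <= table["n_a"] + 1e-9).all()
        assert table["H_o"].between(0, 1).all()
        assert table["H_e"].between(0, 1).all()
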