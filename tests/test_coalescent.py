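"""Coalescent simulator: waiting-time laws, demography inversion, CTMC
evolution along genealogies, and dataset presets."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare, kstest

from msatdemog.coalescent import (ConstantDemography, ExponentialDemography,
                                  Genealogy, PiecewiseDemography,
                                  evolve_microsatellite, kibale_preset,
                                  simulate_dataset, simulate_genealogy)
from msatdemog.genotypes import MISSING, Locus
from msatdemog.mutation import (MutationModel, build_rate_matrix,
                                stationary_distribution)


class TestDemographies:
    def test_piecewise_requires_increasing_change_times(self):
        with pytest.raises(ValueError):
            PiecewiseDemography((1.0, 2.0, 3.0), (2.0, 1.0))
        with pytest.raises(ValueError):
            PiecewiseDemography((1.0, -2.0), (1.0,))

    @pytest.mark.parametrize("dem", [
        ConstantDemography(2.5),
        ExponentialDemography(2.5, 0.8),
        ExponentialDemography(2.5, -0.3),
        PiecewiseDemography((2.5, 0.5, 4.0), (1.0, 3.0)),
    ])
    def test_integrated_rate_matches_quadrature(self, dem):
        val = dem.integrated_rate(0.3, 4.2)
        num, _ = quad(lambda t: 1.0 / dem.theta(t), 0.3, 4.2, limit=200)
        assert val == pytest.approx(num, rel=1e-6)

    @pytest.mark.parametrize("dem", [
        ConstantDemography(2.5),
        ExponentialDemography(2.5, 0.8),
        PiecewiseDemography((2.5, 0.5, 4.0), (1.0, 3.0)),
    ])
    def test_invert_is_inverse_of_integrated_rate(self, dem):
        for t0 in (0.0, 0.7, 2.9):
            for target in (0.05, 0.9, 3.0):
                tau = dem.invert(t0, target)
                assert dem.integrated_rate(t0, t0 + tau) == pytest.approx(
                    target, rel=1e-9)


class TestGenealogySimulation:
    def test_pairwise_mean_is_theta(self, rng):
        theta = 1.7
        times = [simulate_genealogy(2, ConstantDemography(theta), rng).root_height
                 for _ in range(20000)]
        assert np.mean(times) == pytest.approx(theta, rel=0.03)

    def test_tmrca_closed_form(self, rng):
        # E[T_MRCA] = 2 theta (1 - 1/n)
        theta, n = 2.0, 10
        times = [simulate_genealogy(n, ConstantDemography(theta), rng).root_height
                 for _ in range(8000)]
        assert np.mean(times) == pytest.approx(2 * theta * (1 - 1 / n), rel=0.03)

    def test_node_times_increase_rootward(self, rng):
        tree = simulate_genealogy(12, ConstantDemography(1.0), rng)
        par = tree.parents()
        for node in range(tree.root):
            assert tree.times[par[node]] > tree.times[node]

    def test_exponential_demography_time_rescaling(self, rng):
        # n=2 coalescence time: P(T > t) = exp(-I(t)) with
        # I(t) = (e^{g t} - 1)/(g theta0); KS against the inverse transform
        theta0, g = 2.0, 1.1
        dem = ExponentialDemography(theta0, g)
        draws = np.array([
            simulate_genealogy(2, dem, rng).root_height for _ in range(10000)
        ])

        def cdf(t):
            return 1.0 - np.exp(-(np.exp(g * t) - 1.0) / (g * theta0))

        assert kstest(draws, cdf).pvalue > 0.01

    def test_matches_msprime_distribution(self, rng):
        # independent oracle: msprime's Kingman simulator at matching scale
        import msprime

        theta, n = 2.0, 8
        mine = np.array([
            simulate_genealogy(n, ConstantDemography(theta), rng).root_height
            for _ in range(3000)
        ])
        other = []
        for ts in msprime.sim_ancestry(samples=n, ploidy=1,
                                       population_size=theta,
                                       num_replicates=3000, random_seed=11):
            other.append(ts.first().time(ts.first().root))
        assert kstest(mine, np.asarray(other)).pvalue > 0.01

    def test_seeded_runs_bit_reproducible(self):
        a = simulate_genealogy(9, ConstantDemography(1.0),
                               np.random.default_rng(42))
        b = simulate_genealogy(9, ConstantDemography(1.0),
                               np.random.default_rng(42))
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.children, b.children)

    def test_newick_round_trips_through_dendropy(self, rng):
        import dendropy

        tree = simulate_genealogy(6, ConstantDemography(1.0), rng)
        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert len(dt.leaf_nodes()) == 6


class TestEvolveMicrosatellite:
    def test_zero_branch_lengths_copy_root(self, rng):
        n = 6
        tree = Genealogy(n, np.zeros(2 * n - 1),
                         np.array([[0, 1], [6, 2], [7, 3], [8, 4], [9, 5]]))
        model = MutationModel.from_name("EU1", i_min=5, i_max=15)
        tips = evolve_microsatellite(tree, model, rng)
        assert np.unique(tips).size == 1

    def test_long_branches_reach_stationarity(self, rng):
        model = MutationModel.from_name("PC1", i_min=5, i_max=12)
        q = build_rate_matrix(model)
        pi = stationary_distribution(q)
        n = 2
        draws = []
        for _ in range(1500):
            tree = Genealogy(n, np.array([0.0, 0.0, 500.0]), np.array([[0, 1]]))
            draws.extend(evolve_microsatellite(tree, model, rng, q=q))
        obs = np.bincount(np.array(draws) - 5, minlength=len(pi))
        assert chisquare(obs, pi * obs.sum()).pvalue > 0.01

    def test_pairwise_squared_difference_scales_with_length(self, rng):
        # EU1 has step variance 1 and rate 1, so E[(Xa-Xb)^2] ~ L for small L
        model = MutationModel.from_name("EU1", i_min=1, i_max=60)
        q = build_rate_matrix(model)
        total_len = 0.1
        diffs = []
        for _ in range(20000):
            tree = Genealogy(2, np.array([0.0, 0.0, total_len / 2]),
                             np.array([[0, 1]]))
            a, b = evolve_microsatellite(tree, model, rng, q=q)
            diffs.append((a - b) ** 2)
        assert np.mean(diffs) == pytest.approx(total_len, rel=0.15)


class TestSimulateDataset:
    def test_no_missing_when_rate_zero(self, rng):
        loci = [(Locus("L1", repeat_min=1, repeat_max=35),
                 MutationModel.from_name("EU1"))]
        g = simulate_dataset(10, loci, ConstantDemography(2.0), rng,
                             missing_rate=0.0)
        assert (g.calls != MISSING).all()

    def test_missing_rate_injected(self, rng):
        loci = [(Locus("L1", repeat_min=1, repeat_max=35),
                 MutationModel.from_name("EU1"))]
        g = simulate_dataset(200, loci, ConstantDemography(2.0), rng,
                             missing_rate=0.3)
        frac = 1 - g.n_genotyped("L1") / g.n_individuals
        assert frac == pytest.approx(0.3, abs=0.1)

    def test_lattice_mismatch_rejected(self, rng):
        loci = [(Locus("L1", repeat_min=1, repeat_max=30),
                 MutationModel.from_name("EU1", i_min=1, i_max=35))]
        with pytest.raises(ValueError, match="lattice"):
            simulate_dataset(4, loci, ConstantDemography(1.0), rng)

    def test_group_sizes_respected(self, rng):
        loci = [(Locus("L1", repeat_min=1, repeat_max=35),
                 MutationModel.from_name("EU1"))]
        g = simulate_dataset(9, loci, ConstantDemography(2.0), rng,
                             group_sizes={"a": 4, "b": 5}, migration=30.0)
        assert g.groups.count("a") == 4 and g.groups.count("b") == 5

    def test_preset_shape_and_allele_spread(self, rng):
        g = kibale_preset(rng)
        assert g.n_individuals == 85 and g.n_loci == 10
        assert len(g.group_names) == 6
        counts = [np.unique(g.gene_copies(l)).size for l in g.loci]
        # the study observed 3-14 alleles per locus; the preset's spread
        # should bracket that range without collapsing or exploding
        assert min(counts) <= 14 and max(counts) >= 3
        assert 5 <= np.mean(counts) <= 18
        sizes = g.calls[g.calls != MISSING]
        assert sizes.min() >= 1 and sizes.max() <= 35

    def test_preset_reproducible(self):
        a = kibale_preset(np.random.default_rng(7))
        b = kibale_preset(np.random.default_rng(7))
        assert a == b
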