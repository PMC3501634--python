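"""Skyline/constant-size MCMC, marginal likelihoods, model comparison, and
posterior summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import msatdemog as md
from msatdemog.coalescent import PiecewiseDemography, simulate_dataset
from msatdemog.genotypes import Locus
from msatdemog.skyline import (ChainConfig, PriorConfig, SkylinePosterior,
                               compare_models, estimate_lnml,
                               harmonic_mean_lnml, hpd_interval, run_mcmc,
                               stepping_stone_lnml, summarize_posterior)


class TestConfigValidation:
    def test_bad_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=0)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)
        with pytest.raises(ValueError):
            ChainConfig(burn_in=1.0)

    def test_bad_priors_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(lam=0.0)
        with pytest.raises(ValueError):
            PriorConfig(phi_bounds=(1.0, 0.5))

    def test_dem_kind_checked(self):
        with pytest.raises(ValueError):
            run_mcmc(None, None, "LOGISTIC", sample_prior=True)


class TestPriorSampling:
    def test_constant_theta_marginal_is_one_on_x(self):
        lo, hi = 0.1, 10.0
        post = run_mcmc(None, None, "CONSTANT",
                        PriorConfig(theta_bounds=(lo, hi)),
                        ChainConfig(n_iter=60000, thin=10, seed=5),
                        sample_prior=True, n_tips_prior=4)
        # thin further toward independence: the KS test assumes iid draws
        th = np.array([t[0] for t in post.thetas])[::4]

        def cdf(x):
            return np.log(np.asarray(x) / lo) / math.log(hi / lo)

        assert kstest(th, cdf).pvalue > 0.01

    def test_psi_marginal_is_poisson(self):
        # likelihood forced to 1: the change-count marginal must recover
        # its Poisson(ln 2) prior, so P(psi=0) ~ 1/2
        from scipy.stats import chisquare, poisson

        lam = math.log(2.0)
        post = run_mcmc(None, None, "SKYLINE", PriorConfig(time_bound=10.0),
                        ChainConfig(n_iter=8000, thin=2, seed=3),
                        sample_prior=True, n_tips_prior=5)
        assert abs((post.psi == 0).mean() - 0.5) < 0.04
        kmax = 5
        obs = np.bincount(np.clip(post.psi, 0, kmax), minlength=kmax + 1)
        expected = poisson.pmf(np.arange(kmax + 1), lam)
        expected[-1] = 1.0 - expected[:-1].sum()
        # thinned samples are autocorrelated; batch to roughly independent
        # draws before the chi-square
        step = 4
        obs_thin = np.bincount(np.clip(post.psi[::step], 0, kmax),
                               minlength=kmax + 1)
        assert chisquare(obs_thin, expected * obs_thin.sum()).pvalue > 0.01


class TestHpd:
    def test_degenerate_posterior_zero_width(self):
        lo, hi = hpd_interval(np.full(500, 3.3), 0.95)
        assert lo == hi == pytest.approx(3.3)

    def test_uniform_samples_cover_mass(self, rng):
        x = rng.uniform(0, 1, size=20000)
        lo, hi = hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_hpd_is_shortest(self, rng):
        # strongly skewed sample: HPD must be shorter than the central CI
        x = rng.exponential(size=20000)
        lo, hi = hpd_interval(x, 0.95)
        clo, chi = np.quantile(x, [0.025, 0.975])
        assert hi - lo < chi - clo
        assert lo == pytest.approx(0.0, abs=0.05)


def _toy_posterior(n=300, seed=0):
    """Synthetic SkylinePosterior with known trajectories for summaries."""
    rng = np.random.default_rng(seed)
    heights = rng.uniform(1.0, 2.0, size=(n, 3))
    return SkylinePosterior(
        dem_kind="SKYLINE",
        priors=PriorConfig(time_bound=10.0),
        chain=ChainConfig(n_iter=n, burn_in=0.0, thin=1, seed=0),
        locus_names=["a", "b", "c"],
        rate_modifiers=np.ones(3),
        ln_likelihood=np.zeros(n),
        ln_posterior=np.zeros(n),
        psi=np.zeros(n, dtype=int),
        phi=np.ones(n),
        thetas=[np.array([2.0])] * n,
        change_times=[np.array([])] * n,
        root_heights=heights,
        t_coal=heights.max(axis=1),
    )


class TestSummaries:
    def test_t_coal_is_max_root_height(self):
        post = _toy_posterior()
        summ = summarize_posterior(post, grid=np.array([0.0, 0.5]))
        assert summ.t_coal_mean == pytest.approx(post.root_heights.max(axis=1).mean())

    def test_flat_trajectory_has_zero_width_hpd(self):
        post = _toy_posterior()
        summ = summarize_posterior(post, grid=np.array([0.0, 0.5, 1.0]))
        assert (summ.skyline["lower"] == summ.skyline["upper"]).all()
        assert np.allclose(summ.skyline["mean"], 2.0)

    def test_psi_pmf_sums_to_one(self):
        summ = summarize_posterior(_toy_posterior(), grid=np.array([0.0]))
        assert summ.psi_pmf.sum() == pytest.approx(1.0)
        assert summ.psi_pmf.loc[0] == 1.0

    def test_grid_beyond_samples_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            summarize_posterior(_toy_posterior(), grid=np.array([100.0]))

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            summarize_posterior(_toy_posterior(n=50))

    def test_trace_frame_has_standard_columns(self):
        df = _toy_posterior().to_trace_frame()
        for col in ("state", "lnL", "psi", "T_COAL"):
            assert col in df.columns


class TestMarginalLikelihoods:
    def test_constant_likelihood_recovered_by_both_methods(self):
        lnl = np.full(500, -7.25)
        hm, _ = harmonic_mean_lnml(lnl)
        assert hm == pytest.approx(-7.25)
        traces = [(b, lnl) for b in (0.0, 0.25, 0.5, 0.75, 1.0)]
        ss, _ = stepping_stone_lnml(traces)
        assert ss == pytest.approx(-7.25)

    def test_stepping_stone_needs_enough_rungs(self):
        with pytest.raises(ValueError):
            stepping_stone_lnml([(0.0, np.zeros(10)), (1.0, np.zeros(10))])

    @staticmethod
    def _toy_power_samples(beta, n, rng, lo=0.1, hi=10.0):
        """Exact draws from pi_beta(x) ~ (1/x) e^{-beta x} on [lo, hi] by
        grid inversion; returns lnL samples (lnL(x) = -x)."""
        grid = np.linspace(lo, hi, 4000)
        dens = np.exp(-beta * grid) / grid
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        u = rng.uniform(size=n)
        x = np.interp(u, cdf, grid)
        return -x

    def test_stepping_stone_matches_quadrature_on_toy(self, rng):
        # exponential likelihood e^{-x} with a bounded one-on-x prior
        lo, hi = 0.1, 10.0
        grid = np.linspace(lo, hi, 200000)
        z_prior = np.trapezoid(1 / grid, grid)
        truth = math.log(np.trapezoid(np.exp(-grid) / grid, grid) / z_prior)
        betas = [0.0, 0.1, 0.25, 0.45, 0.7, 1.0]
        traces = [(b, self._toy_power_samples(b, 4000, rng)) for b in betas]
        ss, _ = stepping_stone_lnml(traces)
        assert ss == pytest.approx(truth, abs=0.1)

    def test_harmonic_mean_noisier_than_stepping_stone(self, rng):
        betas = [0.0, 0.1, 0.25, 0.45, 0.7, 1.0]
        hm_vals, ss_vals = [], []
        for _ in range(20):
            traces = [(b, self._toy_power_samples(b, 800, rng)) for b in betas]
            ss_vals.append(stepping_stone_lnml(traces)[0])
            hm_vals.append(harmonic_mean_lnml(traces[-1][1])[0])
        assert np.std(hm_vals) > np.std(ss_vals)

    def test_estimate_lnml_dispatch(self):
        with pytest.raises(ValueError):
            estimate_lnml(np.zeros(10), method="BRIDGE")


class TestCompareModels:
    def test_equal_models_tie_without_decisive_label(self):
        comp = compare_models({"a": -10.0, "b": -10.0})
        assert comp.table["ln_bf"].tolist() == [0.0, 0.0]
        assert not comp.table["decisive"].any()

    def test_four_unit_gap_not_decisive(self):
        comp = compare_models({"a": -10.0, "b": -14.0})
        assert comp.table.loc["b", "ln_bf"] == pytest.approx(4.0)
        assert not comp.table.loc["b", "decisive"]

    def test_six_unit_gap_decisive(self):
        comp = compare_models({"a": -10.0, "b": -16.0})
        assert comp.table.loc["b", "ln_bf"] == pytest.approx(6.0)
        assert bool(comp.table.loc["b", "decisive"])

    def test_invariant_to_constant_shift(self):
        base = {"a": -10.0, "b": -13.5, "c": -22.0}
        shifted = {k: v + 100.0 for k, v in base.items()}
        t1 = compare_models(base).table["ln_bf"]
        t2 = compare_models(shifted).table["ln_bf"]
        pd.testing.assert_series_equal(t1, t2)

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            compare_models({"a": -1.0})


class TestInference:
    def test_polymorphism_required(self):
        from conftest import make_matrix

        g = make_matrix([[(10, 10)], [(10, 10)]])
        with pytest.raises(ValueError, match="polymorphic"):
            run_mcmc(g, md.MutationModel.from_name("EU1"), "CONSTANT")

    def test_mcmc_reproducible_for_fixed_seed(self, rng):
        model = md.MutationModel.from_name("EU1", i_min=5, i_max=20)
        loci = [(Locus("L1", repeat_min=5, repeat_max=20), model)]
        g = simulate_dataset(4, loci, md.ConstantDemography(1.0),
                             np.random.default_rng(1))
        kwargs = dict(dem_kind="CONSTANT",
                      priors=PriorConfig(rate_modifiers="none"),
                      chain=ChainConfig(n_iter=400, thin=2, seed=9))
        a = run_mcmc(g, model, **kwargs)
        b = run_mcmc(g, model, **kwargs)
        assert np.array_equal(a.ln_posterior, b.ln_posterior)
        assert np.array_equal(a.t_coal, b.t_coal)

    def test_sharp_decline_shifts_change_count_posterior(self):
        # an 80-fold size contrast at 0.1 mutation units should move the
        # posterior of the change count decisively above its prior mode 0
        model = md.MutationModel.from_name("EU1", i_min=1, i_max=30)
        loci = [(Locus(f"L{j}", repeat_min=1, repeat_max=30), model)
                for j in range(8)]
        truth = PiecewiseDemography((0.1, 8.0), (0.1,))
        g = simulate_dataset(12, loci, truth, np.random.default_rng(1))
        post = run_mcmc(g, model, "SKYLINE",
                        PriorConfig(rate_modifiers="none"),
                        ChainConfig(n_iter=2000, thin=2, seed=1))
        vals, counts = np.unique(post.psi, return_counts=True)
        assert vals[counts.argmax()] >= 1
        assert (post.psi >= 1).mean() > 0.7
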