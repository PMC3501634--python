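"""Bayesian skyline inference of demographic history from a small
simulated microsatellite dataset (scaled down to run in ~1 minute).

The change-point count psi has a Poisson(ln 2) prior, so P(psi = 0) = 1/2
before seeing data; posterior mass staying on psi = 0 is the signature of
a constant-size history.
"""

import numpy as np

import msatdemog as md

theta_true = 2.0
model = md.MutationModel.from_name("EU1", i_min=5, i_max=25)
loci = [(md.Locus(f"L{j}", repeat_min=5, repeat_max=25), model)
        for j in range(4)]
g = md.simulate_dataset(10, loci, md.ConstantDemography(theta_true),
                        np.random.default_rng(5))

post = md.run_mcmc(g, model, "SKYLINE",
                   md.PriorConfig(rate_modifiers="none"),
                   md.ChainConfig(n_iter=2500, thin=2, seed=5))
summ = md.summarize_posterior(post)
print("posterior of change count psi:")
print(summ.psi_pmf.round(3).to_string())
lo, hi = md.hpd_interval(post.theta_at(0.0), 0.95)
print(f"\npresent-day theta: 95% HPD [{lo:.2f}, {hi:.2f}] "
      f"(truth {theta_true})")
print(f"T_COAL mean {summ.t_coal_mean:.2f} mutation units")
years, ne = md.scale_to_natural_units(summ.t_coal_mean, theta_true,
                                      mu=5e-4, generation_time=5.0)
print(f"in natural units: {years:,.0f} years; Ne at truth = {ne:,.0f}")
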