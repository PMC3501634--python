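# msatdemog

Historical demography from microsatellite genotypes: a tested, reusable
Python re-implementation of the analysis pipeline used to ask whether the
Kibale National Park (Uganda) red colobus population — and hence its
rainforest habitat — has been stable through the Late Pleistocene.

The package is aimed at population geneticists who have diploid
repeat-count genotypes (or want realistic synthetic ones) and need, in one
place:

* **Standard statistics** per locus — observed/effective allele numbers
  (n_a, n_e = 1/Σp²), observed and Nei-unbiased expected heterozygosity,
  Hardy–Weinberg and genotypic-disequilibrium permutation G-tests, Weir &
  Cockerham F_IS with randomization and bootstrap, Holm (sequential
  Bonferroni) correction, and a MICRO-CHECKER-style null-allele screen.
* **Structure screening** — R_ST from standardized allele-size variance
  components with permutation tests, 4Nm = (1−R_ST)/R_ST, δμ² group
  distances and the deepest split of their neighbor-joining tree.
* **Bottleneck tests** — the one-tailed Wilcoxon heterozygote-excess test
  under the two-phase mutation model (TPM), the allele-frequency mode-shift
  descriptor, and the Garza–Williamson M-ratio M = k/(r+1) with a
  coalescent simulation null.
* **Twelve microsatellite mutation models** — continuous-time Markov
  chains on a bounded repeat lattice crossing {equal, proportional} rates ×
  {unbiased, constant, linear-logistic} directional bias × {one-step,
  geometric multi-step} step sizes (named EU1 … PL2), with transition
  probabilities and stationary distributions.
* **Coalescent simulation** — genealogies under constant, exponential and
  piecewise-constant θ(t) by exact time-rescaling, symmetric-island
  structured coalescent, and CTMC evolution of repeat counts along the
  trees (the synthetic-data engine that stands in for the undeposited field
  genotypes).
* **Extended-skyline Bayesian inference** — multi-locus MCMC over
  genealogies and a piecewise-constant θ(t) whose number of change points ψ
  is itself inferred (Poisson(λ = ln 2) prior, so P(ψ = 0) = ½), plus a
  constant-size model with a Jeffreys 1/x prior; harmonic-mean and
  stepping-stone marginal likelihoods; ln Bayes-factor model ranking with
  the conventional "decisive > 5" rule; T_COAL (tallest-tree height) and
  N_e summaries with shortest-interval HPDs; conversion to years via
  years = (height/μ)·generation-time and N_e = θ/(4μ).

## Worked example

Simulate a study-shaped dataset (85 diploids, 10 loci, 6 groups with high
gene flow) and screen it for structure and bottlenecks:

```python
import numpy as np
import msatdemog as md

rng = np.random.default_rng(3)
g = md.kibale_preset(rng)

screen = md.rst_screen(g, n_perm=1000, rng=rng)
print(screen.rst_overall, screen.p_overall)
# 0.0093 0.138    -> no detectable structure: one panmictic population

mrt = md.m_ratio_test(g, theta=2.0, n_sim=1000, rng=rng)
print(mrt.m_mean, mrt.m_p)
# 0.920 0.937     -> large M-ratio, non-significant: no recent bottleneck
```

(Values shown are from `examples/03_structure_screen.py` and
`examples/04_bottleneck_tests.py`; the R_ST near zero with p ≫ 0.05 and an
M-ratio near 1 are the signatures of a single stable population.)

Infer the demographic history of a small simulated constant-size dataset
(`examples/06_skyline_inference.py`, ~1 minute):

```python
model = md.MutationModel.from_name("EU1", i_min=5, i_max=25)
loci = [(md.Locus(f"L{j}", repeat_min=5, repeat_max=25), model) for j in range(4)]
g = md.simulate_dataset(10, loci, md.ConstantDemography(2.0), np.random.default_rng(5))
post = md.run_mcmc(g, model, "SKYLINE", md.PriorConfig(rate_modifiers="none"),
                   md.ChainConfig(n_iter=2500, thin=2, seed=5))
print(md.summarize_posterior(post).psi_pmf)
# psi=0 carries the posterior mode -> a constant-size history
```

The printed ψ posterior keeps its mode at 0 and the 95% HPD for θ
([0.81, 3.36]) covers the simulated truth of 2.0 — the same
"no-change-point" reading that, on the real data, indicates tens of
millennia of population (and forest) stability.

Each script in `examples/` is a narrative for one capability and prints
what its numbers mean.  A thin CLI wraps the same pipeline
(`msatdemog all --config cfg.yaml --out results/`), with verbs `simulate`,
`qc`, `sumstats`, `structure`, `bottleneck`, `infer`, `compare`, `all`.

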