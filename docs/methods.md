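# Methods

## Scope and units

All inference operates on diploid microsatellite genotypes recorded as
*repeat counts* on a bounded lattice (default [1, 35]; the cap reflects a
maximum observed allele of 33 repeats with headroom).  Time throughout the
simulation and inference modules is *mutation-scaled*: every mutation model
is normalized so that a lineage accumulates one expected mutation per unit
time at stationarity, and the pairwise coalescence rate at time t is
1/θ(t).  For diploids this makes θ = 4N_e μ, so results convert to natural
units as years = (height/μ)·generation-time and N_e = θ/(4μ).  Defaults are
μ = 5×10⁻⁴ per locus per generation and a 5-year generation time; the
report also prints the 1×10⁻⁴ alternative, under which all times and sizes
scale by exactly five.

## Mutation models

The twelve models cross three axes: per-allele total rate *equal* (α) or
*proportional* (α·(i − i_min + 1)); expansion probability *unbiased* (½),
*constant* (logistic intercept b0), or *linear* (logistic in lattice
position, expit(b0 + b1·(i − i_min))); and step size *one* repeat or
*geometric* on {1, 2, …} with parameter m.  The logistic bias keeps the
expansion probability in (0, 1) for any coefficients, which is why a
logistic rather than linear regression parameterizes directionality.
Boundary handling is direction-truncation: the step-size law is truncated
and renormalized within the chosen direction, and a direction with no room
is dropped, so boundary states mutate at a reduced total rate.  The
"two-step" class is a genuine multi-step geometric law (a mutation may
change the length by one *or more* repeats), not a literal two-repeat cap.
The linear-bias covariate is lattice position (i − i_min), which is
shift-invariant and numerically tame; the proportional-rate law is linear
in the same covariate plus one, a declared convention since no canonical
offset/slope exists.  Named models get mild default bias coefficients
(C: b0 = 0.4; L: b0 = 1, b1 = −0.1, expansion-prone when short and
contraction-prone when long) so that every named model is distinct.

Rate matrices are exponentiated through a cached eigendecomposition;
reversible (one-step) models use the symmetric similarity transform for a
real, numerically clean basis, with scipy's `expm` as the fallback when an
eigenbasis is ill-conditioned.

## Coalescent simulator (the synthetic-data engine)

Genealogies are drawn from the time-inhomogeneous Kingman coalescent by
exact time-rescaling inversion (closed form for constant and exponential
θ(t), segment-walking for piecewise).  Multi-deme datasets use the
symmetric n-island structured coalescent with per-lineage migration rate
M/(2θ), M = 4Nm; diploids pair gene copies within demes (random mating).
Repeat counts evolve along branches by Gillespie simulation from the
model's stationary root state.

The study-shaped preset emulates the data the analysis was designed for:
85 diploids in six groups (32/32/5/5/5/6), 10 loci on [1, 35], high gene
flow (default M = 50, well inside a 25–400 plausible band), and 1% missing
calls.  θ = 2 with a proportional-rate multi-step model (m = 0.8) was
chosen once to match the survey's observed diversity (H_e ≈ 0.72, per-locus
allele counts bracketing 3–14); an equal-rate model at any θ overshoots
heterozygosity because its stationary law is uniform over the lattice.
What the preset does *not* emulate: genotyping error, allele dropout,
family structure within social groups, and locus-specific mutation
spectra — so passing calibration tests on it demonstrates internal
consistency of the methods, not robustness to those artifacts.

## Statistics and tests

Expected heterozygosity uses Nei's unbiased correction (2N/(2N−1))(1−Σp²).
F_IS is the Weir & Cockerham (1984) estimator; the multilocus value is the
ratio of variance components summed over loci, with a percentile bootstrap
across loci for its CI.  HWE and genotypic-disequilibrium G-tests are
permutation tests (gene copies re-paired within a locus; one locus's
genotypes shuffled against the other), avoiding χ² asymptotics on sparse
genotype tables.  All permutation p-values use the add-one rule
(b+1)/(n+1), so p ∈ [1/(n+1), 1].  Multiple testing uses Holm's sequential
Bonferroni with an inclusive boundary.

R_ST standardizes allele sizes per locus by the pooled mean and SD, sums
two-level ANOVA variance components over loci, and permutes individuals
(both gene copies together) among groups.  Negative estimates are reported
as-is; 4Nm = (1−R_ST)/R_ST is reported only for R_ST > 0 — no transform of
a negative R_ST yields a meaningful 4Nm, so it is flagged undefined.  The
null-allele screen uses the single-null-allele closed form
(H_e − H_o)/(1 + H_e) with plain gene diversity, plus a one-sided
homozygote-excess randomization test.

The bottleneck suite follows the two conventional TPM parameterizations:
88% single-step with the geometric multi-step variance set to 12
(heterozygote-excess testing) or the mean set to 2.8 (M-ratio testing);
both are converted internally to the geometric parameter (variance v gives
m = (−1+√(1+4v))/(2v), so v = 12 ⇒ m = ¼).  The heterozygote-excess null
conditions on the observed allele count k by rejection, with θ pre-tuned by
log-scale bisection so k is typical; loci whose conditioning fails within a
bounded number of attempts are dropped with a warning.  The M-ratio null
averages per-locus M over loci within each simulated replicate (the
convention of averaging before simulation is assumed; the alternative is
not documented anywhere authoritative), and requires an explicit θ because
no fitted value is available.  These simulations use an unbounded lattice:
only size differences enter H and M, and the bounded-lattice truncation
would otherwise distort the null for high-diversity loci.

## Skyline inference

The demographic model is piecewise-constant θ(t) with an inferred number of
change points ψ.  Priors: ψ ~ Poisson(λ), default λ = ln 2 ≈ 0.6931 so that
half the prior mass sits on "no change"; change times iid uniform on
(0, T); segment sizes iid Exponential with mean φ; φ (and the constant
model's θ) get the scale-free Jeffreys 1/x prior, made proper on bounded
supports (default [10⁻⁴, 10³]).  T defaults to 8× the initial θ estimate —
safely beyond E[T_MRCA] = 2θ — and is configurable.  Change points are free
parameters updated by reversible-jump birth/death moves rather than
indicators tied to coalescent events (the BEAST-internal scheme); this is a
deliberate divergence chosen for implementability and testability — with
the likelihood switched off, the sampler must reproduce its priors exactly,
and it does (Poisson χ² GOF, truncated-1/x KS in the test suite).

The sampler is Metropolis-within-Gibbs.  Genealogy moves: uniform
node-height slide, root-gap and whole-tree log-scale moves, narrow
exchange, and an independence resimulation from the coalescent prior
(prior terms cancel; acceptance is the pruning-likelihood ratio alone).
Larger trees receive proportionally more elementary moves per sweep.
Demography moves: per-segment θ updates (log-multiplier half the time, an
independence draw from the segment prior otherwise), a joint θ/tree-height
rescale (the classic upDown operator — the two are strongly correlated a
posteriori), φ multiplier, change-time slides between neighbors, and the
birth/death pair whose acceptance reduces to the coalescent-prior ratio
times λ/(ψ+1) or ψ/λ.  The constant model additionally Gibbs-samples θ
from its truncated inverse-gamma full conditional (shape Σ(n_l − 1), scale
the summed coalescent-rate area).  Internal nodes are relabelled into time
order after every tree move, so index bookkeeping never constrains the
state space.

Each diploid contributes its two gene copies as exchangeable haploid tips
(no phasing).  Missing tips carry all-ones partials in the Felsenstein
pruning, whose root is weighted by the model's stationary distribution and
whose partials are rescaled per node against underflow.  Per-locus
mutation-rate modifiers are fixed proportional to the observed allele
count, scaled to mean 1 across loci ("fixed" option; "none" disables
them) — a declared convention, since allele count is the obvious observable
proxy for relative rate.  Polymorphism ascertainment is ignored.

Marginal likelihoods: the harmonic-mean estimator (max-shifted in log
space, block-split MC error) for comparability with the published ranking,
and a stepping-stone estimator over Beta(0.3, 1)-spaced power posteriors as
the lower-variance alternative (the test suite demonstrates both its
agreement with quadrature on a conjugate toy and the harmonic mean's larger
spread).  Model ranking reports ln BF against the best model with the
conventional "decisive > 5" label; relative model probabilities are the
max-shifted softmax of ln mL.  HPDs are shortest contiguous intervals on
sorted samples; T_COAL is the per-sample maximum root height across loci.
Default burn-in is 10% with thinning configurable; every stochastic entry
point takes an explicit seed or generator, and fixed-seed runs are
bit-reproducible.

## Problem sizes in the test suite

The statistical suites run at deliberately small scale chosen to make each
property measurable in minutes on one core: sampler calibration uses 4–5
untyped tips; the quadrature cross-check one diploid at a 21-state lattice
with a 2×10⁵-sweep chain; parameter recovery 20 replicates of 4 loci × 10
diploids; bottleneck calibration 200 (M-ratio) and 40 (heterozygote
excess) replicates of 5–8 loci × 15 diploids; structure calibration 20
replicates of 4 loci × 16 diploids.  These sizes are the package's own
trade-off between statistical resolution and runtime, and the tolerances
(±3 binomial SE, 2% posterior-mean agreement, ≥90% coverage) are matched
to them.

## Known limitations

* The skyline sampler is a research-grade single-chain implementation: no
  parallel tempering, and ESS is only monitored, not enforced.
* Harmonic-mean marginal likelihoods are high-variance; rankings of
  closely matched models should be confirmed with stepping stone.
* The structured coalescent supports only the symmetric island model at
  constant size; no migration-rate inference is attempted.
* The heterozygote-excess null conditions on allele count by rejection,
  which becomes expensive for loci with many alleles in large samples.
* Microsatellite data carry weak signal for change-point detection at
  small sample sizes; the power demonstration in the test suite needs an
  80-fold size contrast to push the ψ posterior decisively off zero.
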