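"""Recent-bottleneck detection from microsatellite data.

Three classic screens: the one-tailed Wilcoxon heterozygote-excess test under
the two-phase mutation model (TPM), the allele-frequency mode-shift
descriptor, and the Garza-Williamson M-ratio with a simulation null.

The TPM mixes single-step mutations (probability ``p_single``) with
geometric multi-step mutations.  The geometric step-size law can be stated
either through its variance (the heterozygote-excess testing convention,
variance 12) or its mean (the M-ratio testing convention, mean 2.8); both
are converted internally to the geometric success parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon

from .coalescent import ConstantDemography, simulate_genealogy
from .genotypes import GenotypeMatrix
from .sumstats import allele_frequencies


@dataclass(frozen=True)
class TPMParams:
    """Two-phase mutation model parameters.

    ``p_single`` is the probability a mutation is +-1; otherwise the
    (absolute) step size is Geometric(m) on {1, 2, ...}.  Exactly one of
    ``step_variance`` / ``step_mean`` fixes the geometric law: with mean
    1/m its variance is (1-m)/m^2.
    """

    p_single: float = 0.88
    step_variance: float | None = None
    step_mean: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_single <= 1:
            raise ValueError("p_single must lie in [0, 1]")
        if (self.step_variance is None) == (self.step_mean is None):
            raise ValueError("state exactly one of step_variance / step_mean")
        if self.step_variance is not None and self.step_variance <= 0:
            raise ValueError("step_variance must be > 0")
        if self.step_mean is not None and self.step_mean < 1:
            raise ValueError("step_mean must be >= 1")

    @property
    def geometric_m(self) -> float:
        """Geometric success parameter implied by the stated variance/mean."""
        if self.step_mean is not None:
            return 1.0 / self.step_mean
        # variance v = (1-m)/m^2  =>  m = (-1 + sqrt(1+4v)) / (2v)
        v = self.step_variance
        return (-1.0 + math.sqrt(1.0 + 4.0 * v)) / (2.0 * v)


#: Heterozygote-excess testing convention: variance of multi-steps = 12.
BOTTLENECK_TPM = TPMParams(p_single=0.88, step_variance=12.0)
#: M-ratio testing convention: 88% single-step, mean multi-step size 2.8.
M_RATIO_TPM = TPMParams(p_single=0.88, step_mean=2.8)


def tpm_step(params: TPMParams, rng: np.random.Generator, size: int | None = None):
    """Signed mutation step(s) under the TPM: +-1 with prob p_single, else a
    +- geometric multi-step of size >= 1 (signs equiprobable)."""
    n = 1 if size is None else size
    mag = np.ones(n, dtype=np.int64)
    multi = rng.random(n) >= params.p_single
    if multi.any():
        mag[multi] = rng.geometric(params.geometric_m, size=int(multi.sum()))
    sign = rng.choice((-1, 1), size=n)
    steps = sign * mag
    return int(steps[0]) if size is None else steps


def simulate_tpm_sample(
    n_copies: int,
    demography,
    params: TPMParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Coalescent TPM sample of allele sizes for `n_copies` gene copies.

    ``demography`` is a theta value (constant size, the equilibrium case
    used by the test nulls) or any :class:`~msatdemog.coalescent.Demography`.
    A genealogy is drawn, mutations fall as a Poisson process (rate 1 per
    lineage per mutation unit), and sizes are relative to the root
    (unbounded lattice, the convention for these tests where only size
    differences matter).
    """
    if isinstance(demography, (int, float)):
        demography = ConstantDemography(float(demography))
    tree = simulate_genealogy(n_copies, demography, rng)
    bl = tree.branch_lengths()
    counts = rng.poisson(bl)
    par = tree.parents()
    sizes = np.zeros(2 * n_copies - 1, dtype=np.int64)
    for node in range(2 * n_copies - 3, -1, -1):
        delta = 0
        c = int(counts[node])
        if c:
            delta = int(tpm_step(params, rng, size=c).sum())
        sizes[node] = sizes[par[node]] + delta
    return sizes[:n_copies]


def _unbiased_het(sample: np.ndarray) -> float:
    n = sample.size
    _, counts = np.unique(sample, return_counts=True)
    p = counts / n
    return (n / (n - 1)) * (1.0 - float(np.sum(p**2)))


def _tune_theta(
    k_target: int,
    n_copies: int,
    params: TPMParams,
    rng: np.random.Generator,
    n_pilot: int = 24,
    iters: int = 10,
) -> float:
    """Bisect theta (log scale) so the equilibrium allele count is typical
    of ``k_target``."""
    lo, hi = math.log(0.02), math.log(80.0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        ks = [np.unique(simulate_tpm_sample(n_copies, math.exp(mid), params, rng)).size
              for _ in range(n_pilot)]
        if np.mean(ks) < k_target:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


@dataclass
class BottleneckReport:
    """Results of the bottleneck screens actually run."""

    dh: dict[str, float] | None = None
    wilcoxon_p: float | None = None
    mode_shift: str | None = None
    m_per_locus: dict[str, float] | None = None
    m_mean: float | None = None
    m_p: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items() if v is not None}


def het_excess_test(
    g: GenotypeMatrix,
    params: TPMParams = BOTTLENECK_TPM,
    n_sim: int = 1000,
    rng: np.random.Generator | None = None,
    max_attempt_factor: int = 60,
) -> BottleneckReport:
    """One-tailed Wilcoxon test for heterozygote excess under the TPM.

    For each polymorphic locus, equilibrium coalescent samples are simulated
    under the TPM conditional on the observed allele count k (rejection on
    k with theta pre-tuned by bisection so k is typical).  The standardized
    excess DH = (H_e_obs - mean H_eq) / SD(H_eq) is combined across loci by
    a one-tailed Wilcoxon signed-rank test for excess.  A recent bottleneck
    inflates H_e relative to the equilibrium expectation at the (reduced)
    observed allele count.
    """
    rng = np.random.default_rng() if rng is None else rng
    dh: dict[str, float] = {}
    for locus in g.loci:
        copies = g.gene_copies(locus)
        k = int(np.unique(copies).size)
        if k < 2:
            continue
        n_copies = copies.size
        he_obs = _unbiased_het(copies)
        theta = _tune_theta(k, n_copies, params, rng)
        h_eq = []
        attempts = 0
        limit = max_attempt_factor * n_sim
        while len(h_eq) < n_sim and attempts < limit:
            attempts += 1
            sample = simulate_tpm_sample(n_copies, theta, params, rng)
            if np.unique(sample).size == k:
                h_eq.append(_unbiased_het(sample))
        if len(h_eq) < max(30, n_sim // 10):
            warnings.warn(
                f"locus {locus.name}: conditioning on k={k} failed "
                f"({len(h_eq)} matches in {attempts} attempts); dropped",
                stacklevel=2,
            )
            continue
        h_eq = np.asarray(h_eq)
        sd = h_eq.std(ddof=1)
        if sd == 0:
            continue
        dh[locus.name] = float((he_obs - h_eq.mean()) / sd)
    if len(dh) < 4:
        raise ValueError(
            f"heterozygote-excess test needs >= 4 usable polymorphic loci, "
            f"got {len(dh)}"
        )
    values = np.array(list(dh.values()))
    p = float(wilcoxon(values, alternative="greater").pvalue)
    return BottleneckReport(dh=dh, wilcoxon_p=p)


def mode_shift(g: GenotypeMatrix) -> str:
    """Mode-shift descriptor of the pooled allele-frequency distribution.

    All per-locus allele frequencies are pooled into ten bins of width 0.1;
    the verdict is ``"L-shaped"`` (no shift, the equilibrium expectation)
    when the lowest-frequency bin holds at least as many alleles as any
    other bin, else ``"shifted"`` (a bottleneck signature).
    """
    if g.n_loci < 5:
        warnings.warn("mode-shift descriptor is unreliable with < 5 loci",
                      stacklevel=2)
    freqs = np.concatenate([
        allele_frequencies(g, locus).to_numpy() for locus in g.loci
    ])
    counts, _ = np.histogram(freqs, bins=np.linspace(0, 1, 11))
    return "L-shaped" if counts[0] >= counts[1:].max() else "shifted"


def m_ratio(copies: np.ndarray) -> float:
    """Garza-Williamson M = k / (r + 1) for one locus's gene copies, with k
    the allele count and r the repeat-count range.  Monomorphic -> 1."""
    alleles = np.unique(copies)
    r = int(alleles.max() - alleles.min())
    return float(alleles.size / (r + 1))


def m_ratio_test(
    g: GenotypeMatrix,
    theta: float,
    params: TPMParams = M_RATIO_TPM,
    n_sim: int = 10000,
    rng: np.random.Generator | None = None,
) -> BottleneckReport:
    """Mean M-ratio across loci against an equilibrium TPM simulation null.

    The observed statistic is the mean of per-locus M = k/(r+1).  Each null
    replicate simulates every locus at equilibrium under the TPM at the
    supplied theta with matching sample sizes and takes the same mean; the
    add-one lower-tail fraction of null means <= observed is the p-value.
    Monomorphic loci contribute M = 1 and are flagged by a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    per_locus: dict[str, float] = {}
    n_copies: list[int] = []
    for locus in g.loci:
        copies = g.gene_copies(locus)
        m = m_ratio(copies)
        if np.unique(copies).size == 1:
            warnings.warn(f"locus {locus.name} monomorphic; M = 1 by convention",
                          stacklevel=2)
        per_locus[locus.name] = m
        n_copies.append(copies.size)
    observed = float(np.mean(list(per_locus.values())))
    hits = 0
    for _ in range(n_sim):
        ms = [m_ratio(simulate_tpm_sample(nc, theta, params, rng))
              for nc in n_copies]
        if float(np.mean(ms)) <= observed + 1e-12:
            hits += 1
    p = (hits + 1) / (n_sim + 1)
    return BottleneckReport(m_per_locus=per_locus, m_mean=observed, m_p=p)
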