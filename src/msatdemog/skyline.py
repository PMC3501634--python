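"""Multi-locus Bayesian inference of demographic history from microsatellite
genotypes: an extended-skyline change-point model and a constant-size model,
with marginal-likelihood estimators and Bayes-factor model ranking.

The demographic trajectory is piecewise-constant with an *inferred* number
of change points psi.  Priors: psi ~ Poisson(lambda) (default
lambda = ln 2 = 0.6931, putting half the prior mass on "no change"); change
times iid Uniform(0, time_bound); segment sizes theta_j iid Exponential with
mean phi; phi gets a one-on-x prior on a bounded support, the scale-free
Jeffreys choice.  The constant-size model puts the one-on-x prior directly
on its single theta.  The sampler is Metropolis-within-Gibbs with
reversible-jump birth/death moves on the number of change points; each
diploid contributes two exchangeable haploid tips per locus.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .coalescent import (ConstantDemography, Demography, Genealogy,
                         PiecewiseDemography, simulate_genealogy)
from .genotypes import MISSING, GenotypeMatrix
from .likelihood import coalescent_loglik, pruning_loglik
from .mutation import MutationModel, SpectralTransitions, build_rate_matrix

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PriorConfig:
    """Priors of the demographic model.

    ``lam`` is the Poisson mean of the change-point count (default ln 2, so
    P(psi = 0) = 1/2); ``phi_bounds`` / ``theta_bounds`` bound the one-on-x
    priors so they are proper; ``psi_max`` truncates the Poisson (kept large
    enough to be immaterial); ``rate_modifiers`` is ``"fixed"`` (per-locus
    modifier proportional to the observed allele count, scaled to mean 1)
    or ``"none"``.
    """

    lam: float = LN2
    phi_bounds: tuple[float, float] = (1e-4, 1e3)
    theta_bounds: tuple[float, float] = (1e-4, 1e3)
    psi_max: int = 30
    time_bound: float | None = None
    rate_modifiers: str = "fixed"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Poisson mean lam must be > 0")
        for lo, hi in (self.phi_bounds, self.theta_bounds):
            if not 0 < lo < hi:
                raise ValueError("one-on-x prior bounds must satisfy 0 < lo < hi")
        if self.rate_modifiers not in ("fixed", "none"):
            raise ValueError("rate_modifiers must be 'fixed' or 'none'")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings: total sweeps, burn-in fraction, thinning, seed."""

    n_iter: int = 20000
    burn_in: float = 0.10
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.thin <= 0:
            raise ValueError("chain length and thinning must be positive")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn-in fraction must lie in [0, 1)")


@dataclass
class SkylinePosterior:
    """Thinned posterior samples from :func:`run_mcmc`."""

    dem_kind: str
    priors: PriorConfig
    chain: ChainConfig
    locus_names: list[str]
    rate_modifiers: np.ndarray
    ln_likelihood: np.ndarray          # data log likelihood per sample
    ln_posterior: np.ndarray
    psi: np.ndarray
    phi: np.ndarray
    thetas: list[np.ndarray]           # per sample: segment sizes (psi+1,)
    change_times: list[np.ndarray]     # per sample: sorted times (psi,)
    root_heights: np.ndarray           # (n_samples, n_loci)
    t_coal: np.ndarray                 # per sample max root height
    trees: list[list[Genealogy]] | None = None
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.ln_likelihood)

    def theta_at(self, t: float) -> np.ndarray:
        """theta(t) across samples (vectorized over the posterior)."""
        out = np.empty(self.n_samples)
        for i in range(self.n_samples):
            ct = self.change_times[i]
            j = int(np.searchsorted(ct, t, side="right"))
            out[i] = self.thetas[i][j]
        return out

    def to_trace_frame(self) -> pd.DataFrame:
        """Tab-separated-log style trace: one row per retained sample."""
        df = pd.DataFrame({
            "state": np.arange(self.n_samples) * self.chain.thin,
            "lnL": self.ln_likelihood,
            "lnPosterior": self.ln_posterior,
            "psi": self.psi,
            "phi": self.phi,
            "theta0": [th[0] for th in self.thetas],
            "T_COAL": self.t_coal,
        })
        for j, name in enumerate(self.locus_names):
            df[f"rootHeight.{name}"] = self.root_heights[:, j]
        return df


# -- internal sampler state --------------------------------------------------


class _State:
    def __init__(self, trees, tip_states, trans, modifiers, dem_kind, priors,
                 theta_init, power):
        self.trees: list[Genealogy] = trees
        self.tips = tip_states
        self.trans: SpectralTransitions | None = trans
        self.modifiers = modifiers
        self.dem_kind = dem_kind
        self.priors = priors
        self.power = power
        self.phi = theta_init
        self.thetas = np.array([theta_init])
        self.times = np.array([])  # sorted change times
        self.model: MutationModel | None = None
        self.lnl_locus = np.zeros(len(trees))   # pruning lnL per locus
        self.coal_locus = np.zeros(len(trees))  # coalescent prior per locus

    # demography object for the current parameters
    def demography(self) -> Demography:
        if len(self.thetas) == 1:
            return ConstantDemography(float(self.thetas[0]))
        return PiecewiseDemography(tuple(self.thetas), tuple(self.times))

    def pruning(self, locus: int, tree: Genealogy | None = None) -> float:
        if self.power == 0.0 or self.trans is None:
            return 0.0
        tree = self.trees[locus] if tree is None else tree
        ll = pruning_loglik(self.tips[locus], tree, self.model,
                            rate_modifier=float(self.modifiers[locus]),
                            trans=self.trans)
        return self.power * ll

    def coal(self, locus: int, tree=None, dem=None) -> float:
        tree = self.trees[locus] if tree is None else tree
        dem = self.demography() if dem is None else dem
        return coalescent_loglik(tree, dem)

    def refresh(self) -> None:
        dem = self.demography()
        for l in range(len(self.trees)):
            self.lnl_locus[l] = self.pruning(l)
            self.coal_locus[l] = self.coal(l, dem=dem)

    def log_hyperprior(self) -> float:
        """Priors on psi, change times, thetas, phi (excluding trees)."""
        pr = self.priors
        psi = len(self.times)
        lp = psi * math.log(pr.lam) - math.lgamma(psi + 1) - pr.lam
        if self.dem_kind == "SKYLINE":
            # change-time set density: psi! / time_bound^psi
            lp += math.lgamma(psi + 1) - psi * math.log(pr.time_bound)
            lp += float(np.sum(-np.log(self.phi) - self.thetas / self.phi))
            lp += -math.log(self.phi)  # one-on-x on phi (unnormalized)
        else:
            lp = -math.log(float(self.thetas[0]))  # one-on-x on theta
        return lp

    def ln_posterior(self) -> float:
        return (float(self.lnl_locus.sum()) + float(self.coal_locus.sum())
                + self.log_hyperprior())


def _smm_theta_estimate(g: GenotypeMatrix) -> float:
    """Moment estimate of theta from mean expected heterozygosity under a
    stepwise model: theta = ((1/(1-He))^2 - 1) / 2."""
    from .sumstats import heterozygosities

    hes = []
    for locus in g.loci:
        try:
            _, he = heterozygosities(g, locus)
        except ValueError:
            continue
        if 0 < he < 0.98:
            hes.append(he)
    if not hes:
        return 1.0
    he = float(np.mean(hes))
    return ((1.0 / (1.0 - he)) ** 2 - 1.0) / 2.0


def rate_modifiers_from_allele_counts(g: GenotypeMatrix) -> np.ndarray:
    """Fixed per-locus mutation-rate modifiers proportional to the observed
    allele count, scaled to mean 1 across loci."""
    counts = []
    for locus in g.loci:
        copies = g.gene_copies(locus)
        counts.append(max(1, np.unique(copies).size))
    k = np.asarray(counts, dtype=float)
    return k / k.mean()


def run_mcmc(
    g: GenotypeMatrix | None,
    model: MutationModel | None,
    dem_kind: str = "SKYLINE",
    priors: PriorConfig = PriorConfig(),
    chain: ChainConfig = ChainConfig(),
    sample_prior: bool = False,
    power: float = 1.0,
    n_tips_prior: int = 10,
    n_loci_prior: int = 1,
    store_trees: bool = False,
) -> SkylinePosterior:
    """Metropolis-within-Gibbs sampler over genealogies and demography.

    Per sweep, every locus receives one genealogy move (node-height slide,
    root scale, whole-tree scale, or narrow exchange) and the demography
    receives a block of moves (theta scale, phi scale, change-time slide,
    and a reversible-jump birth/death step when ``dem_kind="SKYLINE"``).

    With ``sample_prior=True`` (or ``power=0``) the data likelihood is
    replaced by 1 and the chain samples the joint prior, which is how the
    sampler's correctness is audited; ``g`` and ``model`` may then be None.
    ``power`` scales the log likelihood for power-posterior (stepping-stone)
    runs.
    """
    if dem_kind not in ("CONSTANT", "SKYLINE"):
        raise ValueError("dem_kind must be CONSTANT or SKYLINE")
    rng = np.random.default_rng(chain.seed)
    if sample_prior:
        power = 0.0

    if g is not None:
        tip_states = []
        locus_names = []
        for locus in g.loci:
            calls = g.locus_calls(locus)
            tips = calls.ravel().copy()  # 2N exchangeable haploid tips
            tip_states.append(tips)
            locus_names.append(locus.name)
        if not any((t != MISSING).any() and np.unique(t[t != MISSING]).size > 1
                   for t in tip_states):
            raise ValueError("need at least one polymorphic locus")
        modifiers = (rate_modifiers_from_allele_counts(g)
                     if priors.rate_modifiers == "fixed"
                     else np.ones(g.n_loci))
        theta_init = min(max(_smm_theta_estimate(g), priors.theta_bounds[0] * 10),
                         priors.theta_bounds[1] / 10)
        n_tips = [len(t) for t in tip_states]
    else:
        if power != 0.0:
            raise ValueError("data-free runs require sample_prior=True")
        tip_states = [np.full(n_tips_prior, MISSING)] * n_loci_prior
        locus_names = [f"locus{j + 1}" for j in range(n_loci_prior)]
        modifiers = np.ones(n_loci_prior)
        theta_init = 1.0
        n_tips = [n_tips_prior] * n_loci_prior

    trans = None
    if power != 0.0:
        if model is None:
            raise ValueError("a mutation model is required when the likelihood is on")
        trans = SpectralTransitions(build_rate_matrix(model))

    time_bound = priors.time_bound
    if time_bound is None:
        time_bound = 8.0 * theta_init
    priors = PriorConfig(lam=priors.lam, phi_bounds=priors.phi_bounds,
                         theta_bounds=priors.theta_bounds, psi_max=priors.psi_max,
                         time_bound=time_bound,
                         rate_modifiers=priors.rate_modifiers)

    trees = [simulate_genealogy(nt, ConstantDemography(theta_init), rng)
             for nt in n_tips]
    state = _State(trees, tip_states, trans, modifiers, dem_kind, priors,
                   theta_init, power)
    state.model = model
    state.refresh()

    n_keep = 0
    burn = int(chain.n_iter * chain.burn_in)
    samples = {k: [] for k in
               ("lnL", "lnPost", "psi", "phi", "thetas", "times", "heights")}
    kept_trees: list[list[Genealogy]] = []
    acc = {k: [0, 0] for k in
           ("height", "root", "scale", "exchange", "resim", "theta", "updown",
            "phi", "time", "rj")}

    def mh(delta: float) -> bool:
        return delta >= 0 or rng.random() < math.exp(delta)

    L = len(state.trees)
    # larger trees need several elementary moves per sweep to keep the
    # genealogy mixing in step with the demography
    moves_per_locus = [max(1, nt // 6) for nt in n_tips]
    for it in range(chain.n_iter):
        for l in range(L):
            for _ in range(moves_per_locus[l]):
                _tree_move(state, l, rng, acc)
        _theta_move(state, rng, acc)
        if rng.random() < 0.5:  # touches every locus's pruning: keep occasional
            _updown_move(state, rng, acc)
        if dem_kind == "CONSTANT":
            _theta_gibbs_constant(state, rng)
        if dem_kind == "SKYLINE":
            _phi_move(state, rng, acc)
            if len(state.times):
                _time_move(state, rng, acc)
            _rj_move(state, rng, acc)
        if it >= burn and (it - burn) % chain.thin == 0:
            n_keep += 1
            samples["lnL"].append(float(state.lnl_locus.sum()) /
                                  (power if power else 1.0))
            samples["lnPost"].append(state.ln_posterior())
            samples["psi"].append(len(state.times))
            samples["phi"].append(float(state.phi))
            samples["thetas"].append(state.thetas.copy())
            samples["times"].append(state.times.copy())
            samples["heights"].append([t.root_height for t in state.trees])
            if store_trees:
                kept_trees.append([
                    Genealogy(t.n_tips, t.times.copy(), t.children.copy(),
                              list(t.labels))
                    for t in state.trees
                ])

    lnl = np.asarray(samples["lnL"])
    if power != 0.0 and n_keep >= 10:
        ess = _ess(lnl)
        if ess < 100:
            logger.warning("low effective sample size for lnL: %.0f", ess)
    heights = np.asarray(samples["heights"])
    return SkylinePosterior(
        dem_kind=dem_kind,
        priors=priors,
        chain=chain,
        locus_names=locus_names,
        rate_modifiers=modifiers,
        ln_likelihood=lnl,
        ln_posterior=np.asarray(samples["lnPost"]),
        psi=np.asarray(samples["psi"], dtype=int),
        phi=np.asarray(samples["phi"]),
        thetas=samples["thetas"],
        change_times=samples["times"],
        root_heights=heights,
        t_coal=heights.max(axis=1),
        trees=kept_trees if store_trees else None,
        acceptance={k: (v[0] / v[1] if v[1] else float("nan"))
                    for k, v in acc.items()},
    )


def _ess(x: np.ndarray) -> float:
    """Effective sample size by initial-positive-sequence autocorrelation."""
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    tau = 1.0
    for lag in range(1, min(n // 2, 1000)):
        if acf[lag] <= 0:
            break
        tau += 2.0 * acf[lag]
    return n / tau


# -- individual moves --------------------------------------------------------


def _canonical(tree: Genealogy) -> Genealogy:
    """Relabel internal nodes in time order (the index invariant of
    :class:`Genealogy`); raises ValueError if a parent-child time ordering
    is violated.  Proposals may scramble the time order of unrelated
    internal nodes; the tree itself is unchanged by this relabelling."""
    n = tree.n_tips
    order = np.argsort(tree.times[n:], kind="stable")
    new_id = np.empty(n - 1, dtype=np.int64)
    new_id[order] = np.arange(n - 1)
    times = tree.times.copy()
    times[n:] = tree.times[n:][order]
    children = tree.children[order].copy()
    internal = children >= n
    children[internal] = new_id[children[internal] - n] + n
    return Genealogy(n, times, children, list(tree.labels))


def _accept(state: _State, delta: float, rng, acc, key) -> bool:
    acc[key][1] += 1
    ok = delta >= 0 or rng.random() < math.exp(delta)
    if ok:
        acc[key][0] += 1
    return ok


def _tree_move(state: _State, l: int, rng, acc) -> None:
    tree = state.trees[l]
    n = tree.n_tips
    kind = rng.choice(("height", "root", "scale", "exchange", "resim"))
    if kind in ("exchange", "height") and n < 3:
        kind = "root"
    if kind == "resim":
        # independence proposal from the coalescent prior: the prior terms
        # cancel and acceptance depends on the pruning likelihood alone
        dem = state.demography()
        new = simulate_genealogy(n, dem, rng, labels=list(tree.labels))
        new_lnl = state.pruning(l, tree=new)
        if _accept(state, new_lnl - state.lnl_locus[l], rng, acc, "resim"):
            state.trees[l] = new
            state.lnl_locus[l] = new_lnl
            state.coal_locus[l] = state.coal(l, tree=new, dem=dem)
        return
    new = Genealogy(tree.n_tips, tree.times.copy(), tree.children.copy(),
                    list(tree.labels), check=False)
    log_hastings = 0.0
    if kind == "height":
        # slide one non-root internal node uniformly between its children
        # and parent
        k = int(rng.integers(0, n - 2))  # internal nodes n..2n-3 (not root)
        node = n + k
        par = tree.parents()
        lo = float(max(tree.times[c] for c in tree.children[k]))
        hi = float(tree.times[par[node]])
        if hi <= lo:
            return
        new.times[node] = rng.uniform(lo, hi)
    elif kind == "root":
        root = tree.root
        cmax = float(max(tree.times[c] for c in tree.children[root - n]))
        gap = float(tree.times[root]) - cmax
        delta = rng.uniform(-0.7, 0.7)
        new.times[root] = cmax + gap * math.exp(delta)
        log_hastings = delta
    elif kind == "scale":
        delta = rng.uniform(-0.3, 0.3)
        new.times[n:] = tree.times[n:] * math.exp(delta)
        log_hastings = (n - 1) * delta
    else:  # narrow exchange
        k = int(rng.integers(0, n - 2))  # pick non-root internal node v
        v = n + k
        par = tree.parents()
        p = par[v]
        sib = [c for c in tree.children[p - n] if c != v][0]
        child = int(tree.children[k][rng.integers(0, 2)])
        if tree.times[sib] >= tree.times[v]:
            return
        cv = new.children[k]
        cp = new.children[p - n]
        cv[cv == child] = sib
        cp[cp == sib] = child
    try:
        new = _canonical(new)
    except ValueError:
        return
    dem = state.demography()
    new_lnl = state.pruning(l, tree=new)
    new_coal = state.coal(l, tree=new, dem=dem)
    delta_lp = (new_lnl + new_coal) - (state.lnl_locus[l] + state.coal_locus[l])
    if _accept(state, delta_lp + log_hastings, rng, acc, kind):
        state.trees[l] = new
        state.lnl_locus[l] = new_lnl
        state.coal_locus[l] = new_coal


def _coal_rate_area(tree: Genealogy) -> float:
    """Integral of C(k,2) dt over the tree: theta * (coalescent rate mass)
    under a constant demography."""
    coal = np.sort(tree.coalescence_times())
    k = tree.n_tips
    area = 0.0
    t_prev = 0.0
    for t in coal:
        area += k * (k - 1) / 2.0 * (float(t) - t_prev)
        t_prev = float(t)
        k -= 1
    return area


def _theta_gibbs_constant(state: _State, rng) -> None:
    """Exact Gibbs update of the constant-model theta.

    Given the genealogies, theta has an inverse-gamma full conditional with
    shape sum(n_l - 1) (the one-on-x prior contributes the final unit) and
    scale equal to the summed coalescent-rate area, truncated to the prior
    bounds."""
    from scipy.special import gammaincc, gammainccinv

    shape = sum(t.n_tips - 1 for t in state.trees)
    scale = sum(_coal_rate_area(t) for t in state.trees)
    if scale <= 0:
        return
    lo, hi = state.priors.theta_bounds
    # CDF of IG(shape, scale) at x is gammaincc(shape, scale/x)
    c_lo, c_hi = gammaincc(shape, scale / lo), gammaincc(shape, scale / hi)
    if not np.isfinite(c_lo) or not np.isfinite(c_hi) or c_hi - c_lo < 1e-12:
        return
    theta = scale / float(gammainccinv(shape, rng.uniform(c_lo, c_hi)))
    if not lo <= theta <= hi:
        return
    state.thetas = np.array([theta])
    dem = ConstantDemography(theta)
    state.coal_locus = np.array([state.coal(l, dem=dem)
                                 for l in range(len(state.trees))])


def _theta_move(state: _State, rng, acc) -> None:
    """Update one theta segment: a log-scale multiplier half the time, an
    independence draw from the segment prior otherwise (the prior and the
    proposal cancel, so the acceptance ratio is the coalescent-prior
    ratio alone — this carries the chain across the full prior range)."""
    j = int(rng.integers(0, len(state.thetas)))
    old = float(state.thetas[j])
    lo, hi = state.priors.theta_bounds
    if rng.random() < 0.5:
        delta = rng.uniform(-0.7, 0.7)
        new = old * math.exp(delta)
        if state.dem_kind == "CONSTANT" and not lo <= new <= hi:
            return
        if state.dem_kind == "CONSTANT":
            log_prior_ratio = math.log(old / new)  # one-on-x
        else:
            log_prior_ratio = -(new - old) / state.phi  # exponential(phi)
        log_correction = log_prior_ratio + delta  # prior + Hastings
    else:
        if state.dem_kind == "CONSTANT":
            new = lo * (hi / lo) ** rng.random()  # draw from truncated 1/x
        else:
            new = float(rng.exponential(state.phi))
            if new <= 0:
                return
        log_correction = 0.0  # proposal equals the prior
    thetas = state.thetas.copy()
    thetas[j] = new
    dem = (ConstantDemography(float(thetas[0])) if len(thetas) == 1
           else PiecewiseDemography(tuple(thetas), tuple(state.times)))
    new_coal = np.array([state.coal(l, dem=dem) for l in range(len(state.trees))])
    delta_lp = float(new_coal.sum() - state.coal_locus.sum()) + log_correction
    if _accept(state, delta_lp, rng, acc, "theta"):
        state.thetas = thetas
        state.coal_locus = new_coal


def _updown_move(state: _State, rng, acc) -> None:
    """Jointly rescale all theta segments and all genealogy node times.

    Population size and tree depth are strongly correlated a posteriori;
    scaling them together (the classic upDown operator) decorrelates the
    chain.  Change times are left untouched."""
    delta = rng.uniform(-0.4, 0.4)
    c = math.exp(delta)
    thetas = state.thetas * c
    lo, hi = state.priors.theta_bounds
    if state.dem_kind == "CONSTANT" and not lo <= thetas[0] <= hi:
        return
    new_trees = []
    for tree in state.trees:
        times = tree.times.copy()
        times[tree.n_tips:] *= c
        new_trees.append(Genealogy(tree.n_tips, times, tree.children.copy(),
                                   list(tree.labels), check=False))
    if state.dem_kind == "CONSTANT":
        log_prior_ratio = -len(thetas) * delta  # one-on-x per theta
    else:
        log_prior_ratio = -float((thetas - state.thetas).sum()) / state.phi
    dem = (ConstantDemography(float(thetas[0])) if len(thetas) == 1
           else PiecewiseDemography(tuple(thetas), tuple(state.times)))
    new_lnl = np.array([state.pruning(l, tree=new_trees[l])
                        for l in range(len(new_trees))])
    new_coal = np.array([state.coal(l, tree=new_trees[l], dem=dem)
                         for l in range(len(new_trees))])
    n_scaled = len(thetas) + sum(t.n_tips - 1 for t in state.trees)
    delta_lp = (float(new_lnl.sum() + new_coal.sum())
                - float(state.lnl_locus.sum() + state.coal_locus.sum())
                + log_prior_ratio)
    if _accept(state, delta_lp + n_scaled * delta, rng, acc, "updown"):
        state.trees = new_trees
        state.thetas = thetas
        state.lnl_locus = new_lnl
        state.coal_locus = new_coal


def _phi_move(state: _State, rng, acc) -> None:
    old = state.phi
    delta = rng.uniform(-0.7, 0.7)
    new = old * math.exp(delta)
    lo, hi = state.priors.phi_bounds
    if not lo <= new <= hi:
        return
    k = len(state.thetas)
    s = float(state.thetas.sum())
    # Exp(phi) likelihood of thetas + one-on-x prior on phi
    delta_lp = (-k * math.log(new) - s / new) - (-k * math.log(old) - s / old)
    delta_lp += math.log(old / new)
    if _accept(state, delta_lp + delta, rng, acc, "phi"):
        state.phi = new


def _time_move(state: _State, rng, acc) -> None:
    psi = len(state.times)
    r = int(rng.integers(0, psi))
    lo = 0.0 if r == 0 else float(state.times[r - 1])
    hi = state.priors.time_bound if r == psi - 1 else float(state.times[r + 1])
    times = state.times.copy()
    times[r] = rng.uniform(lo, hi)
    dem = PiecewiseDemography(tuple(state.thetas), tuple(times))
    new_coal = np.array([state.coal(l, dem=dem) for l in range(len(state.trees))])
    delta_lp = float(new_coal.sum() - state.coal_locus.sum())
    if _accept(state, delta_lp, rng, acc, "time"):
        state.times = times
        state.coal_locus = new_coal


def _rj_move(state: _State, rng, acc) -> None:
    """Reversible-jump birth/death of one change point.

    Birth draws a new time uniformly on (0, time_bound) and a new size for
    the older half of the split segment from Exponential(phi); with those
    proposal choices the prior terms cancel and the acceptance ratio is the
    coalescent-prior ratio times lambda/(psi+1) (birth) or psi/lambda
    (death).
    """
    psi = len(state.times)
    birth = (rng.random() < 0.5) if 0 < psi < state.priors.psi_max else (psi == 0)
    lam = state.priors.lam
    if birth:
        u = rng.uniform(0.0, state.priors.time_bound)
        j = int(np.searchsorted(state.times, u, side="right"))
        theta_new = rng.exponential(state.phi)
        if theta_new <= 0:
            return
        times = np.insert(state.times, j, u)
        thetas = np.insert(state.thetas, j + 1, theta_new)
        log_move = math.log(lam / (psi + 1))
        # asymmetric move-choice probabilities at the boundaries
        p_birth = 1.0 if psi == 0 else 0.5
        p_death_rev = 0.5 if psi + 1 < state.priors.psi_max else 1.0
        log_move += math.log(p_death_rev / p_birth)
    else:
        r = int(rng.integers(0, psi))
        times = np.delete(state.times, r)
        thetas = np.delete(state.thetas, r + 1)
        log_move = math.log(psi / lam)
        p_death = 1.0 if psi == state.priors.psi_max else 0.5
        p_birth_rev = 0.5 if psi > 1 else 1.0
        log_move += math.log(p_birth_rev / p_death)
    dem = (ConstantDemography(float(thetas[0])) if len(thetas) == 1
           else PiecewiseDemography(tuple(thetas), tuple(times)))
    new_coal = np.array([state.coal(l, dem=dem) for l in range(len(state.trees))])
    delta_lp = float(new_coal.sum() - state.coal_locus.sum()) + log_move
    if _accept(state, delta_lp, rng, acc, "rj"):
        state.times = times
        state.thetas = thetas
        state.coal_locus = new_coal


# -- marginal likelihoods and model comparison -------------------------------


def harmonic_mean_lnml(ln_likelihoods: np.ndarray) -> tuple[float, float]:
    """Harmonic-mean estimate of ln marginal likelihood, with a block MC
    error.  Computed in log space with max-shift stabilization."""
    lnl = np.asarray(ln_likelihoods, dtype=float)
    if lnl.size == 0:
        raise ValueError("empty log-likelihood trace")
    est = -(logsumexp(-lnl) - math.log(lnl.size))
    n_block = min(10, max(2, lnl.size // 10))
    blocks = np.array_split(lnl, n_block)
    ests = [-(logsumexp(-b) - math.log(b.size)) for b in blocks if b.size]
    err = float(np.std(ests, ddof=1) / math.sqrt(len(ests)))
    return float(est), err


def stepping_stone_lnml(
    power_traces: list[tuple[float, np.ndarray]],
) -> tuple[float, float]:
    """Stepping-stone estimate of ln mL from power-posterior lnL traces.

    ``power_traces`` holds (beta, lnL samples) pairs; betas must include 0
    and 1 and at least 4 rungs.  ln mL = sum over adjacent rungs of the log
    mean importance ratio exp((b_{k+1} - b_k) lnL) under the b_k run.
    """
    traces = sorted(power_traces, key=lambda t: t[0])
    betas = [t[0] for t in traces]
    if len(betas) < 4:
        raise ValueError("stepping stone needs at least 4 power-posterior runs")
    if not (math.isclose(betas[0], 0.0) and math.isclose(betas[-1], 1.0)):
        raise ValueError("beta grid must span 0 to 1")
    total = 0.0
    var = 0.0
    for (b0, lnl0), (b1, _) in zip(traces[:-1], traces[1:]):
        w = (b1 - b0) * np.asarray(lnl0, dtype=float)
        total += logsumexp(w) - math.log(w.size)
        var += float(np.var(np.exp(w - w.max()))) / w.size
    return float(total), math.sqrt(var)


def estimate_lnml(source, method: str = "HARMONIC_MEAN") -> tuple[float, float]:
    """ln marginal likelihood (+ MC error) from a posterior or power runs.

    ``method="HARMONIC_MEAN"`` takes a :class:`SkylinePosterior` (or raw lnL
    trace); ``method="STEPPING_STONE"`` takes a list of (beta, lnL trace)
    power-posterior pairs.
    """
    if method == "HARMONIC_MEAN":
        lnl = source.ln_likelihood if isinstance(source, SkylinePosterior) \
            else np.asarray(source)
        return harmonic_mean_lnml(lnl)
    if method == "STEPPING_STONE":
        return stepping_stone_lnml(source)
    raise ValueError("method must be HARMONIC_MEAN or STEPPING_STONE")


def run_stepping_stone(
    g: GenotypeMatrix,
    model: MutationModel,
    dem_kind: str = "CONSTANT",
    priors: PriorConfig = PriorConfig(),
    chain: ChainConfig = ChainConfig(),
    n_rungs: int = 8,
    alpha: float = 0.3,
) -> tuple[float, float]:
    """Convenience driver: run power posteriors on a Beta(alpha, 1)-spaced
    beta grid (plus beta = 0) and combine with the stepping-stone estimator."""
    betas = [0.0] + [((k + 1) / n_rungs) ** (1.0 / alpha) for k in range(n_rungs)]
    traces = []
    for i, beta in enumerate(betas):
        cfg = ChainConfig(n_iter=chain.n_iter, burn_in=chain.burn_in,
                          thin=chain.thin, seed=chain.seed + 1000 * i)
        if beta == 0.0:
            post = run_mcmc(g, model, dem_kind, priors, cfg, power=1e-12)
        else:
            post = run_mcmc(g, model, dem_kind, priors, cfg, power=beta)
        traces.append((beta, post.ln_likelihood))
    return stepping_stone_lnml(traces)


@dataclass
class ModelComparison:
    """Ranked ln marginal likelihoods with ln Bayes factors vs. the best."""

    table: pd.DataFrame  # index: model name; columns: ln_ml, mc_error, ln_bf, decisive

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


#: ln Bayes factor above which support is conventionally called decisive.
DECISIVE_LN_BF = 5.0


def compare_models(
    lnmls: dict[str, float | tuple[float, float]],
) -> ModelComparison:
    """Rank models by ln mL and report ln BF = ln mL_best - ln mL_i.

    Values may be bare ln mL floats or (ln mL, MC error) pairs.  Models
    with ln BF > 5 against them are labelled decisively rejected.
    """
    if len(lnmls) < 2:
        raise ValueError("need at least 2 models to compare")
    rows = []
    for name, v in lnmls.items():
        ml, err = (v if isinstance(v, (tuple, list)) else (v, float("nan")))
        rows.append((name, float(ml), float(err)))
    df = pd.DataFrame(rows, columns=["model", "ln_ml", "mc_error"])
    df = df.sort_values("ln_ml", ascending=False).set_index("model")
    best = df["ln_ml"].iloc[0]
    df["ln_bf"] = best - df["ln_ml"]
    df["decisive"] = df["ln_bf"] > DECISIVE_LN_BF
    return ModelComparison(table=df)


# -- posterior summaries -----------------------------------------------------


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding `mass` of the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("no samples")
    k = max(1, int(math.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


@dataclass
class SkylineSummary:
    skyline: pd.DataFrame           # time, mean, median, lower, upper
    t_coal_mean: float
    t_coal_hpd: tuple[float, float]
    psi_pmf: pd.Series

    def to_tsv(self, path) -> None:
        self.skyline.to_csv(path, sep="\t", index=False)


def summarize_posterior(
    post: SkylinePosterior,
    grid: np.ndarray | None = None,
    mass: float = 0.95,
) -> SkylineSummary:
    """Skyline table (mean/median/HPD of theta(t) on a time grid), T_COAL
    summary, and the posterior pmf of the change-point count."""
    if post.n_samples < 100:
        raise ValueError("need >= 100 retained samples to summarize")
    if grid is None:
        grid = np.linspace(0.0, float(np.median(post.t_coal)), 25)
    grid = np.asarray(grid, dtype=float)
    tmax = float(post.t_coal.max())
    if grid.min() > tmax:
        warnings.warn("grid lies beyond all sampled root heights; truncated",
                      stacklevel=2)
        grid = np.array([0.0])
    rows = []
    for t in grid:
        th = post.theta_at(float(t))
        lo, hi = hpd_interval(th, mass)
        rows.append((t, float(th.mean()), float(np.median(th)), lo, hi))
    sky = pd.DataFrame(rows, columns=["time", "mean", "median", "lower", "upper"])
    lo, hi = hpd_interval(post.t_coal, mass)
    psi_vals, psi_counts = np.unique(post.psi, return_counts=True)
    pmf = pd.Series(psi_counts / post.psi.size, index=psi_vals, name="p")
    return SkylineSummary(
        skyline=sky,
        t_coal_mean=float(post.t_coal.mean()),
        t_coal_hpd=(lo, hi),
        psi_pmf=pmf,
    )
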