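"""Coalescent genealogies under parametric demographies, microsatellite
evolution along them, and synthetic diploid datasets.

Time is measured in mutation units before the present: the pairwise
coalescence rate at time t is 1/theta(t), and each mutation-model CTMC is
normalized to one expected mutation per lineage per unit time, so
theta = 4*Ne*mu for diploid data.  E[T_MRCA] of an n-sample at constant
theta is 2*theta*(1 - 1/n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, Locus
from .mutation import MutationModel, build_rate_matrix, stationary_distribution


# -- demographies ------------------------------------------------------------


class Demography:
    """theta(t) trajectory; subclasses provide exact integrated rates."""

    def theta(self, t: float) -> float:
        raise NotImplementedError

    def integrated_rate(self, t0: float, t1: float) -> float:
        """Integral of dt/theta(t) over [t0, t1]."""
        raise NotImplementedError

    def invert(self, t0: float, target: float) -> float:
        """Smallest tau with integral_{t0}^{t0+tau} dt/theta(t) = target."""
        raise NotImplementedError

    # vectorized forms used by the likelihoods; subclasses may override
    def theta_vec(self, t: np.ndarray) -> np.ndarray:
        return np.array([self.theta(float(x)) for x in t])

    def cumulative_rate(self, t: np.ndarray) -> np.ndarray:
        """Integral of du/theta(u) from 0 to each entry of t."""
        return np.array([self.integrated_rate(0.0, float(x)) for x in t])


@dataclass(frozen=True)
class ConstantDemography(Demography):
    theta0: float

    def __post_init__(self) -> None:
        if self.theta0 <= 0:
            raise ValueError("theta must be > 0")

    def theta(self, t: float) -> float:
        return self.theta0

    def integrated_rate(self, t0: float, t1: float) -> float:
        return (t1 - t0) / self.theta0

    def invert(self, t0: float, target: float) -> float:
        return target * self.theta0

    def theta_vec(self, t: np.ndarray) -> np.ndarray:
        return np.full(len(t), self.theta0)

    def cumulative_rate(self, t: np.ndarray) -> np.ndarray:
        return np.asarray(t, dtype=float) / self.theta0


@dataclass(frozen=True)
class ExponentialDemography(Demography):
    """theta(t) = theta0 * exp(-growth * t): with growth > 0 the population
    was smaller in the past (growth toward the present)."""

    theta0: float
    growth: float

    def __post_init__(self) -> None:
        if self.theta0 <= 0:
            raise ValueError("theta0 must be > 0")

    def theta(self, t: float) -> float:
        return self.theta0 * math.exp(-self.growth * t)

    def integrated_rate(self, t0: float, t1: float) -> float:
        g = self.growth
        if g == 0:
            return (t1 - t0) / self.theta0
        return (math.exp(g * t1) - math.exp(g * t0)) / (g * self.theta0)

    def invert(self, t0: float, target: float) -> float:
        g = self.growth
        if g == 0:
            return target * self.theta0
        arg = math.exp(g * t0) + g * self.theta0 * target
        if arg <= 0:  # declining-into-the-past trajectory may never coalesce
            return math.inf
        return math.log(arg) / g - t0

    def theta_vec(self, t: np.ndarray) -> np.ndarray:
        return self.theta0 * np.exp(-self.growth * np.asarray(t, dtype=float))

    def cumulative_rate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        g = self.growth
        if g == 0:
            return t / self.theta0
        return (np.exp(g * t) - 1.0) / (g * self.theta0)


@dataclass(frozen=True)
class PiecewiseDemography(Demography):
    """Piecewise-constant theta: value thetas[j] on [times[j], times[j+1]),
    with times[0] = 0 implied and the last segment extending to infinity.

    ``change_times`` are the strictly increasing epoch boundaries (length
    one less than ``thetas``).
    """

    thetas: tuple[float, ...]
    change_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thetas) != len(self.change_times) + 1:
            raise ValueError("need exactly one more theta than change time")
        if any(th <= 0 for th in self.thetas):
            raise ValueError("all thetas must be > 0")
        if any(b <= a for a, b in zip(self.change_times, self.change_times[1:])):
            raise ValueError("change times must be strictly increasing")
        if self.change_times and self.change_times[0] <= 0:
            raise ValueError("change times must be positive")

    def theta(self, t: float) -> float:
        j = np.searchsorted(self.change_times, t, side="right")
        return self.thetas[j]

    def integrated_rate(self, t0: float, t1: float) -> float:
        bounds = (0.0, *self.change_times, math.inf)
        total = 0.0
        for j, th in enumerate(self.thetas):
            lo, hi = max(t0, bounds[j]), min(t1, bounds[j + 1])
            if hi > lo:
                total += (hi - lo) / th
        return total

    def theta_vec(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.change_times, np.asarray(t, dtype=float),
                              side="right")
        return np.asarray(self.thetas, dtype=float)[idx]

    def cumulative_rate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        times = np.asarray(self.change_times, dtype=float)
        thetas = np.asarray(self.thetas, dtype=float)
        widths = np.diff(np.concatenate(([0.0], times)))
        prefix = np.concatenate(([0.0], np.cumsum(widths / thetas[:-1])))
        idx = np.searchsorted(times, t, side="right")
        seg_start = np.concatenate(([0.0], times))[idx]
        return prefix[idx] + (t - seg_start) / thetas[idx]

    def invert(self, t0: float, target: float) -> float:
        bounds = (0.0, *self.change_times, math.inf)
        t = t0
        remaining = target
        j = int(np.searchsorted(self.change_times, t0, side="right"))
        while j < len(self.thetas):
            th = self.thetas[j]
            seg_end = bounds[j + 1]
            capacity = (seg_end - t) / th
            if remaining <= capacity:
                return (t + remaining * th) - t0
            remaining -= capacity
            t = seg_end
            j += 1
        return math.inf  # unreachable: last segment has infinite capacity


# -- genealogies -------------------------------------------------------------


@dataclass
class Genealogy:
    """Rooted binary tree with node times (0 at the tips, increasing rootward).

    Nodes 0..n-1 are tips; nodes n..2n-2 are internal, created in coalescence
    order so node times are non-decreasing with the index.  ``children[k]``
    holds the two children of internal node n+k.
    """

    n_tips: int
    times: np.ndarray          # (2n-1,)
    children: np.ndarray       # (n-1, 2)
    labels: list[str] = field(default_factory=list)
    check: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.children = np.asarray(self.children, dtype=np.int64)
        if not self.labels:
            self.labels = [f"t{i}" for i in range(self.n_tips)]
        if self.check:
            self.validate()

    def validate(self) -> None:
        n = self.n_tips
        if self.times.shape != (2 * n - 1,) or self.children.shape != (n - 1, 2):
            raise ValueError("inconsistent genealogy arrays")
        if n > 1:
            child_times = self.times[self.children]
            parent_times = self.times[n:, None]
            if not (parent_times > child_times - 1e-12).all():
                raise ValueError("parent time must exceed child time")

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    @property
    def root_height(self) -> float:
        return float(self.times[self.root])

    def parents(self) -> np.ndarray:
        par = np.full(2 * self.n_tips - 1, -1, dtype=np.int64)
        for k in range(self.n_tips - 1):
            par[self.children[k]] = self.n_tips + k
        return par

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (root entry is 0)."""
        par = self.parents()
        bl = np.zeros(2 * self.n_tips - 1)
        nz = par >= 0
        bl[nz] = self.times[par[nz]] - self.times[nz]
        return bl

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def coalescence_times(self) -> np.ndarray:
        return self.times[self.n_tips:]

    def to_newick(self) -> str:
        bl = self.branch_lengths()

        def rec(node: int) -> str:
            if node < self.n_tips:
                return f"{self.labels[node]}:{bl[node]:.8g}"
            a, b = self.children[node - self.n_tips]
            inner = f"({rec(a)},{rec(b)})"
            return inner if node == self.root else f"{inner}:{bl[node]:.8g}"

        return rec(self.root) + ";"


def simulate_genealogy(
    n: int,
    dem: Demography,
    rng: np.random.Generator,
    labels: list[str] | None = None,
) -> Genealogy:
    """Kingman coalescent genealogy of n tips under a demography.

    Waiting times come from the time-inhomogeneous coalescent with rate
    C(k,2)/theta(t), drawn by exact time-rescaling inversion.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    times = np.zeros(2 * n - 1)
    children = np.zeros((n - 1, 2), dtype=np.int64)
    active = list(range(n))
    t = 0.0
    for k in range(n, 1, -1):
        pair_rate = k * (k - 1) / 2.0
        target = rng.exponential() / pair_rate
        t += dem.invert(t, target)
        i, j = rng.choice(len(active), size=2, replace=False)
        if i > j:
            i, j = j, i
        new = 2 * n - k  # next internal node index
        times[new] = t
        children[new - n] = (active[i], active[j])
        active[j] = new
        del active[i]
    return Genealogy(n_tips=n, times=times, children=children,
                     labels=labels or [])


def _simulate_island_genealogy(
    deme_of_tip: np.ndarray,
    theta_deme: float,
    migration: float,
    rng: np.random.Generator,
) -> Genealogy:
    """Structured coalescent under the symmetric n-island model.

    Within-deme pairwise coalescence rate 1/theta_deme; each lineage
    migrates at rate M/(2*theta_deme) where M = 4*N*m is the scaled
    migration rate, landing in a uniform random other deme.
    """
    n = len(deme_of_tip)
    d = int(deme_of_tip.max()) + 1
    if d > 1 and migration <= 0:
        raise ValueError("migration must be > 0 with more than one deme")
    times = np.zeros(2 * n - 1)
    children = np.zeros((n - 1, 2), dtype=np.int64)
    lineage = list(range(n))
    deme = list(int(x) for x in deme_of_tip)
    mig_rate = migration / (2.0 * theta_deme)
    t = 0.0
    next_node = n
    while len(lineage) > 1:
        counts = np.bincount(deme, minlength=d)
        coal_rates = counts * (counts - 1) / 2.0 / theta_deme
        total_mig = len(lineage) * mig_rate if d > 1 else 0.0
        total = coal_rates.sum() + total_mig
        t += rng.exponential() / total
        if rng.random() < coal_rates.sum() / total:
            # coalescence: pick deme by rate, then a pair within it
            probs = coal_rates / coal_rates.sum()
            target_deme = rng.choice(d, p=probs)
            members = [ix for ix, dm in enumerate(deme) if dm == target_deme]
            i, j = rng.choice(len(members), size=2, replace=False)
            i, j = sorted((members[i], members[j]))
            times[next_node] = t
            children[next_node - n] = (lineage[i], lineage[j])
            lineage[j] = next_node
            deme[j] = target_deme
            del lineage[i], deme[i]
            next_node += 1
        else:
            i = int(rng.integers(len(lineage)))
            shift = int(rng.integers(1, d))
            deme[i] = (deme[i] + shift) % d
    return Genealogy(n_tips=n, times=times, children=children)


# -- mutation along the tree -------------------------------------------------


def evolve_microsatellite(
    tree: Genealogy,
    model: MutationModel,
    rng: np.random.Generator,
    q: np.ndarray | None = None,
) -> np.ndarray:
    """Repeat counts at the tips after CTMC evolution along the genealogy.

    The root state is drawn from the model's stationary distribution and
    each branch is simulated with the Gillespie algorithm.
    """
    if q is None:
        q = build_rate_matrix(model)
    pi = stationary_distribution(q)
    s = q.shape[0]
    exit_rates = -np.diag(q)
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = jump / jump.sum(axis=1, keepdims=True)
    jump = np.nan_to_num(jump)

    n = tree.n_tips
    par = tree.parents()
    states = np.zeros(2 * n - 1, dtype=np.int64)
    states[tree.root] = rng.choice(s, p=pi)
    bl = tree.branch_lengths()
    # visit internal nodes root-down (decreasing index), then tips inherit
    for node in range(2 * n - 3, -1, -1):
        state = states[par[node]]
        remaining = bl[node]
        while True:
            rate = exit_rates[state]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= remaining:
                break
            remaining -= wait
            state = rng.choice(s, p=jump[state])
        states[node] = state
    return states[:n] + model.i_min


# -- datasets ----------------------------------------------------------------


def simulate_dataset(
    n_ind: int,
    loci: list[tuple[Locus, MutationModel]],
    dem: Demography,
    rng: np.random.Generator,
    group_sizes: dict[str, int] | None = None,
    migration: float | None = None,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Synthetic diploid genotype matrix under the coalescent + CTMC models.

    For a single group the 2*n_ind gene copies of each locus share one
    panmictic genealogy; with several groups a symmetric-island structured
    coalescent is used (``migration`` = scaled 4Nm; both gene copies of an
    individual live in its group's deme).  ``dem`` must be a
    :class:`ConstantDemography` when groups are structured.  Missing calls
    are injected independently at ``missing_rate``.
    """
    if n_ind < 2:
        raise ValueError("need at least 2 individuals")
    if group_sizes is None:
        group_sizes = {"pop1": n_ind}
    if sum(group_sizes.values()) != n_ind:
        raise ValueError("group sizes must sum to n_ind")
    groups: list[str] = []
    for name, size in group_sizes.items():
        groups.extend([name] * size)
    d = len(group_sizes)
    if d > 1:
        if migration is None or migration <= 0:
            raise ValueError("structured dataset needs migration (4Nm) > 0")
        if not isinstance(dem, ConstantDemography):
            raise ValueError("structured simulation supports constant demography only")
    deme_names = list(group_sizes)
    deme_idx = {name: i for i, name in enumerate(deme_names)}
    deme_of_copy = np.repeat([deme_idx[g] for g in groups], 2)

    calls = np.zeros((n_ind, len(loci), 2), dtype=np.int64)
    for j, (locus, model) in enumerate(loci):
        if (model.i_min, model.i_max) != (locus.repeat_min, locus.repeat_max):
            raise ValueError(
                f"locus {locus.name}: lattice {locus.repeat_min, locus.repeat_max} "
                f"does not match model lattice {model.i_min, model.i_max}"
            )
        if d == 1:
            tree = simulate_genealogy(2 * n_ind, dem, rng)
        else:
            tree = _simulate_island_genealogy(
                deme_of_copy, dem.theta0, migration, rng
            )
        tips = evolve_microsatellite(tree, model, rng)
        calls[:, j, 0] = tips[0::2]
        calls[:, j, 1] = tips[1::2]
    if missing_rate > 0:
        mask = rng.random((n_ind, len(loci))) < missing_rate
        calls[mask] = MISSING
    ids = [f"ind{i + 1:03d}" for i in range(n_ind)]
    return GenotypeMatrix(
        ids=ids, groups=groups, loci=[l for l, _ in loci], calls=calls
    )


def kibale_preset(
    rng: np.random.Generator,
    theta: float = 2.0,
    migration: float = 50.0,
    missing_rate: float = 0.01,
    model_name: str = "PU2",
    step_m: float = 0.8,
) -> GenotypeMatrix:
    """Synthetic stand-in for the Kibale red colobus field genotypes.

    Emulates the study's data shape: 85 diploid individuals in six social
    groups (two large study groups of 32 each and four smaller groups),
    10 microsatellite loci on a [1, 35] repeat lattice, high gene flow
    between groups (scaled 4Nm well above 25), and a sprinkle of missing
    calls.  The defaults (theta = 2 in mutation-scaled units with a mildly
    dispersed multi-step law) reproduce the study's expected heterozygosity
    of ~0.72 with a per-locus allele-count spread bracketing the observed
    3-14.
    """
    group_sizes = {
        "LargeMikana": 32, "SmallCamp": 32, "Dura": 5,
        "K30": 5, "Mainaro": 5, "Sebatoli": 6,
    }
    model = MutationModel.from_name(model_name, i_min=1, i_max=35, m=step_m)
    loci = [
        (Locus(name=f"L{j + 1:02d}", motif_length=4 if j < 7 else 2,
               repeat_min=1, repeat_max=35), model)
        for j in range(10)
    ]
    return simulate_dataset(
        n_ind=85,
        loci=loci,
        dem=ConstantDemography(theta),
        rng=rng,
        group_sizes=group_sizes,
        migration=migration,
        missing_rate=missing_rate,
    )
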