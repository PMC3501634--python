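"""Per-locus diversity statistics, HWE/LD permutation G-tests, F_IS, and
population-structure screening (R_ST, 4Nm, delta-mu^2 distances, NJ split).

Conventions: expected heterozygosity uses Nei's unbiased small-sample
correction; F_IS is the Weir & Cockerham (1984) estimator with the
multilocus weighted mean formed as the ratio of variance components summed
over loci; permutation p-values use the add-one rule (b+1)/(n+1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, Locus, allele_frequencies


# -- diversity ---------------------------------------------------------------


def effective_alleles(freqs) -> float:
    """Effective number of alleles, 1 / sum(p_i^2)."""
    p = np.asarray(freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("frequencies must sum to 1")
    return float(1.0 / np.sum(p**2))


def heterozygosities(g: GenotypeMatrix, locus: Locus | str) -> tuple[float, float]:
    """(H_o, H_e): observed heterozygote proportion and Nei's unbiased
    expected heterozygosity (2N/(2N-1)) (1 - sum p_i^2)."""
    calls = g.locus_calls(locus)[g.genotyped_mask(locus)]
    if calls.size == 0:
        raise ValueError("no non-missing calls")
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    p = allele_frequencies(g, locus).to_numpy()
    two_n = 2 * len(calls)
    if p.size == 1:
        return 0.0, 0.0
    he = (two_n / (two_n - 1)) * (1.0 - float(np.sum(p**2)))
    return ho, he


@dataclass
class LocusSummary:
    name: str
    N: int
    n_a: int
    n_e: float
    H_o: float
    H_e: float
    F_IS: float = float("nan")
    p_HWE: float = float("nan")


def locus_summaries(
    g: GenotypeMatrix,
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-locus table of N, n_a, n_e, H_o, H_e (+ F_IS, HWE p if requested)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fis_per_locus, _, _ = fis(g, n_rand=0, n_boot=0, rng=rng)
    rows = []
    for locus in g.loci:
        p = allele_frequencies(g, locus)
        ho, he = heterozygosities(g, locus)
        row = LocusSummary(
            name=locus.name,
            N=g.n_genotyped(locus),
            n_a=len(p),
            n_e=effective_alleles(p.to_numpy()),
            H_o=ho,
            H_e=he,
            F_IS=fis_per_locus.get(locus.name, float("nan")),
        )
        if n_perm and len(p) >= 2:
            row.p_HWE = hwe_gtest(g, locus, n_perm=n_perm, rng=rng)
        rows.append(row)
    return pd.DataFrame([vars(r) for r in rows])


# -- G-tests -----------------------------------------------------------------


def _g_statistic(obs: np.ndarray, exp: np.ndarray) -> float:
    """G = 2 sum obs ln(obs/exp) over cells with positive expectation."""
    mask = (obs > 0) & (exp > 0)
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))


def _hwe_g(calls: np.ndarray) -> float:
    """G statistic of genotype counts against Hardy-Weinberg expectations."""
    n = len(calls)
    copies = calls.ravel()
    alleles, counts = np.unique(copies, return_counts=True)
    p = counts / copies.size
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    obs = np.zeros((k, k))
    for a, b in calls:
        i, j = sorted((idx[a], idx[b]))
        obs[i, j] += 1
    exp = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            exp[i, j] = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
    return _g_statistic(obs, exp)


def hwe_gtest(
    g: GenotypeMatrix,
    locus: Locus | str,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation G-test of Hardy-Weinberg proportions at one locus.

    The null distribution is generated by shuffling the 2N gene copies among
    individuals (random re-pairing); p is the add-one upper-tail probability.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng() if rng is None else rng
    calls = g.locus_calls(locus)[g.genotyped_mask(locus)]
    copies = calls.ravel()
    if np.unique(copies).size < 2:
        raise ValueError("HWE test requires >= 2 alleles")
    g_obs = _hwe_g(calls)
    hits = 0
    n = len(calls)
    for _ in range(n_perm):
        perm = rng.permutation(copies).reshape(n, 2)
        if _hwe_g(perm) >= g_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def ld_gtest(
    g: GenotypeMatrix,
    locus_a: Locus | str,
    locus_b: Locus | str,
    n_perm: int = 4500,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation G-test of genotypic disequilibrium between two loci.

    Builds the two-locus genotype contingency table over individuals typed
    at both loci and permutes one locus's genotypes among individuals.
    """
    rng = np.random.default_rng() if rng is None else rng
    ca = g.locus_calls(locus_a)
    cb = g.locus_calls(locus_b)
    ok = (ca != MISSING).all(axis=1) & (cb != MISSING).all(axis=1)
    if not ok.any():
        raise ValueError("no individuals genotyped at both loci")
    ca, cb = ca[ok], cb[ok]
    # encode each unordered genotype as a single integer label
    base = max(int(ca.max()), int(cb.max())) + 1
    ga = ca[:, 0] * base + ca[:, 1]
    gb = cb[:, 0] * base + cb[:, 1]
    for arr in (ga, gb):
        if np.unique(arr).size < 2:
            raise ValueError("both loci must be polymorphic among shared individuals")

    def g_of(a, b):
        tab = pd.crosstab(a, b).to_numpy().astype(float)
        exp = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        return _g_statistic(tab, exp)

    g_obs = g_of(ga, gb)
    hits = 0
    for _ in range(n_perm):
        if g_of(ga, rng.permutation(gb)) >= g_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# -- F_IS --------------------------------------------------------------------


def _wc_components(calls: np.ndarray) -> tuple[float, float]:
    """Weir & Cockerham (1984) single-sample variance components (b, c)
    summed over alleles: b = among-individual, c = within-individual.
    F_IS = 1 - c/(b + c)."""
    n = len(calls)
    copies = calls.ravel()
    alleles = np.unique(copies)
    b_sum = c_sum = 0.0
    for a in alleles:
        p = float((copies == a).mean())
        h = float(((calls[:, 0] == a) ^ (calls[:, 1] == a)).mean())
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2.0
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def fis(
    g: GenotypeMatrix,
    n_rand: int = 10000,
    n_boot: int = 10000,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> tuple[dict[str, float], float, tuple[float, float]]:
    """Weir & Cockerham F_IS per locus, weighted multilocus mean, bootstrap CI.

    The weighted mean is the ratio of variance components summed over loci
    (FSTAT convention).  Significance per locus (when ``n_rand`` > 0) is by
    randomizing gene copies among individuals; the CI (when ``n_boot`` > 1)
    is the percentile bootstrap over loci.  Monomorphic loci are skipped
    with a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    per_locus: dict[str, float] = {}
    comps: list[tuple[float, float]] = []
    for locus in g.loci:
        calls = g.locus_calls(locus)[g.genotyped_mask(locus)]
        if len(calls) < 2 or np.unique(calls.ravel()).size < 2:
            warnings.warn(f"locus {locus.name} monomorphic; skipped in F_IS",
                          stacklevel=2)
            continue
        b, c = _wc_components(calls)
        per_locus[locus.name] = 1.0 - c / (b + c) if (b + c) != 0 else float("nan")
        comps.append((b, c))
    if not comps:
        return per_locus, float("nan"), (float("nan"), float("nan"))
    bs = np.array([bc[0] for bc in comps])
    cs = np.array([bc[1] for bc in comps])
    weighted = 1.0 - cs.sum() / (bs.sum() + cs.sum())
    if n_boot > 1 and len(comps) >= 2:
        idx = rng.integers(0, len(comps), size=(n_boot, len(comps)))
        num = cs[idx].sum(axis=1)
        den = bs[idx].sum(axis=1) + num
        boot = 1.0 - num / den
        lo, hi = np.quantile(boot, [(1 - ci_level) / 2, (1 + ci_level) / 2])
        ci = (float(lo), float(hi))
    else:
        ci = (float("nan"), float("nan"))
    return per_locus, float(weighted), ci


def fis_randomization_p(
    g: GenotypeMatrix,
    locus: Locus | str,
    n_rand: int = 10000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided randomization p for one locus's F_IS (alleles shuffled
    among individuals)."""
    rng = np.random.default_rng() if rng is None else rng
    calls = g.locus_calls(locus)[g.genotyped_mask(locus)]
    b, c = _wc_components(calls)
    f_obs = 1.0 - c / (b + c)
    copies = calls.ravel()
    n = len(calls)
    hits = 0
    for _ in range(n_rand):
        perm = rng.permutation(copies).reshape(n, 2)
        b, c = _wc_components(perm)
        if abs(1.0 - c / (b + c)) >= abs(f_obs) - 1e-12:
            hits += 1
    return (hits + 1) / (n_rand + 1)


# -- multiple testing --------------------------------------------------------


def sequential_bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm's sequential Bonferroni: sort p ascending and reject while
    p_(i) <= alpha/(m - i + 1); stop at the first failure.  Boundary
    inclusive.  Returns a boolean array aligned with the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags


# -- structure screen --------------------------------------------------------


@dataclass
class StructureScreen:
    """R_ST / 4Nm permutation screen plus delta-mu^2 NJ split."""

    rst_overall: float
    p_overall: float
    four_nm: float | None
    pairwise_rst: pd.DataFrame
    pairwise_p: pd.DataFrame
    pairwise_significant: pd.DataFrame
    delta_mu2: pd.DataFrame | None = None
    nj_newick: str | None = None
    deepest_split: tuple[tuple[str, ...], tuple[str, ...]] | None = None

    def to_json_dict(self) -> dict:
        return {
            "rst_overall": self.rst_overall,
            "p_overall": self.p_overall,
            "four_nm": self.four_nm,
            "pairwise_rst": self.pairwise_rst.to_dict(),
            "pairwise_p": self.pairwise_p.to_dict(),
            "delta_mu2": None if self.delta_mu2 is None else self.delta_mu2.to_dict(),
            "nj_newick": self.nj_newick,
            "deepest_split": self.deepest_split,
        }


def _standardized_sizes(g: GenotypeMatrix) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per locus: (standardized gene-copy sizes, individual index of each copy).

    Sizes are standardized with the global (all groups pooled) mean and SD,
    the allele-size standardization used for R_ST.
    """
    out = []
    for locus in g.loci:
        mask = g.genotyped_mask(locus)
        calls = g.locus_calls(locus)[mask].astype(float)
        ind = np.nonzero(mask)[0]
        sizes = calls.ravel()
        sd = sizes.std(ddof=1)
        if sd == 0:
            continue
        std = (sizes - sizes.mean()) / sd
        out.append((std, np.repeat(ind, 2)))
    return out


def _rst_from_labels(
    per_locus: list[tuple[np.ndarray, np.ndarray]],
    labels: np.ndarray,
) -> float:
    """R_ST from summed ANOVA variance components of standardized sizes.

    labels: group index per individual (length n_individuals); both gene
    copies of an individual carry its label.
    """
    s_among = s_within = 0.0
    for sizes, ind in per_locus:
        grp = labels[ind]
        groups = np.unique(grp)
        a = groups.size
        if a < 2:
            continue
        n_i = np.array([(grp == gr).sum() for gr in groups], dtype=float)
        n_tot = n_i.sum()
        means = np.array([sizes[grp == gr].mean() for gr in groups])
        grand = sizes.mean()
        ss_among = float(np.sum(n_i * (means - grand) ** 2))
        ss_within = float(sum(((sizes[grp == gr] - mu) ** 2).sum()
                              for gr, mu in zip(groups, means)))
        ms_among = ss_among / (a - 1)
        dfw = n_tot - a
        if dfw <= 0:
            continue
        ms_within = ss_within / dfw
        n0 = (n_tot - np.sum(n_i**2) / n_tot) / (a - 1)
        s_within += ms_within
        s_among += (ms_among - ms_within) / n0
    denom = s_among + s_within
    return float(s_among / denom) if denom > 0 else 0.0


def rst_screen(
    g: GenotypeMatrix,
    n_perm: int = 10000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> StructureScreen:
    """Overall and pairwise R_ST with permutation tests, and 4Nm.

    Allele sizes are standardized per locus with the pooled mean/SD; variance
    components come from a two-level ANOVA summed across loci.  Negative
    estimates are reported as-is.  The permutation unit is the individual
    (both gene copies move together).  Pairwise p-values get a sequential
    Bonferroni correction.  4Nm = (1 - R_ST)/R_ST when R_ST > 0, else None.
    """
    rng = np.random.default_rng() if rng is None else rng
    names = [gr for gr in g.group_names
             if sum(x == gr for x in g.groups) >= 2]
    dropped = set(g.group_names) - set(names)
    if dropped:
        warnings.warn(f"groups with < 2 individuals excluded: {sorted(dropped)}",
                      stacklevel=2)
    if len(names) < 2:
        raise ValueError("R_ST needs >= 2 groups of >= 2 individuals")
    g = g.subset_groups(names)
    per_locus = _standardized_sizes(g)
    gidx = {name: i for i, name in enumerate(names)}
    labels = np.array([gidx[x] for x in g.groups])

    def perm_p(pl, lab):
        obs = _rst_from_labels(pl, lab)
        hits = 0
        for _ in range(n_perm):
            if _rst_from_labels(pl, rng.permutation(lab)) >= obs - 1e-12:
                hits += 1
        return obs, (hits + 1) / (n_perm + 1)

    rst, p = perm_p(per_locus, labels)
    four_nm = (1.0 - rst) / rst if rst > 0 else None

    k = len(names)
    pw = np.zeros((k, k))
    pwp = np.ones((k, k))
    pair_ps = []
    pairs = list(itertools.combinations(range(k), 2))
    for i, j in pairs:
        sub = g.subset_groups([names[i], names[j]])
        sub_pl = _standardized_sizes(sub)
        sub_lab = np.array([0 if x == names[i] else 1 for x in sub.groups])
        r_ij, p_ij = perm_p(sub_pl, sub_lab)
        pw[i, j] = pw[j, i] = r_ij
        pwp[i, j] = pwp[j, i] = p_ij
        pair_ps.append(p_ij)
    sig = sequential_bonferroni(pair_ps, alpha=alpha)
    sig_mat = np.zeros((k, k), dtype=bool)
    for (i, j), s in zip(pairs, sig):
        sig_mat[i, j] = sig_mat[j, i] = bool(s)
    return StructureScreen(
        rst_overall=rst,
        p_overall=p,
        four_nm=four_nm,
        pairwise_rst=pd.DataFrame(pw, index=names, columns=names),
        pairwise_p=pd.DataFrame(pwp, index=names, columns=names),
        pairwise_significant=pd.DataFrame(sig_mat, index=names, columns=names),
    )


def delta_mu2(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise delta-mu^2 distances between groups: the squared difference
    of mean allele size, averaged over loci."""
    names = g.group_names
    means = np.zeros((len(names), g.n_loci))
    valid = np.zeros((len(names), g.n_loci), dtype=bool)
    for a, name in enumerate(names):
        sub = g.subset_groups([name])
        for j, locus in enumerate(g.loci):
            copies = sub.gene_copies(locus)
            if copies.size:
                means[a, j] = copies.mean()
                valid[a, j] = True
    d = np.zeros((len(names), len(names)))
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ok = valid[a] & valid[b]
            d[a, b] = d[b, a] = float(((means[a, ok] - means[b, ok]) ** 2).mean())
    return pd.DataFrame(d, index=names, columns=names)


def delta_mu2_nj(g: GenotypeMatrix) -> StructureScreen | pd.DataFrame:
    """Delta-mu^2 distance matrix, neighbor-joining tree, and deepest split.

    With only two groups, returns the distance matrix alone.  The deepest
    split is the bipartition of groups induced by the longest internal
    branch of the unrooted NJ tree; ties break toward the lexicographically
    smallest bipartition.  Returns (distances, newick, (side_a, side_b)).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = delta_mu2(g)
    names = list(d.index)
    if len(names) < 3:
        return d, None, None
    dm = DistanceMatrix(d.to_numpy(), ids=names)
    tree = nj(dm)
    all_tips = frozenset(names)
    best = None  # (length, sorted side tuple)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue  # external-ish edge: not an internal bipartition
        length = node.length or 0.0
        canon = tuple(sorted(side)) if min(side) <= min(all_tips - side) \
            else tuple(sorted(all_tips - side))
        key = (length, tuple(sorted(canon, reverse=True)))
        if best is None or length > best[0] + 1e-15 or (
            abs(length - best[0]) <= 1e-15 and canon < best[1]
        ):
            best = (length, canon)
    if best is None:
        split = None
    else:
        side_a = best[1]
        side_b = tuple(sorted(all_tips - set(side_a)))
        split = (side_a, side_b)
    return d, str(tree).strip(), split
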