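"""Diploid microsatellite genotype matrices: data model, GenePop/CSV I/O, locus QC.

Allele coordinates throughout the package are *repeat counts*, not fragment
lengths.  Genotyping software usually emits allele codes (fragment sizes or
bins); each :class:`Locus` therefore carries a ``code_offset`` so that
``repeat = code - code_offset`` (identity mapping by default).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele call.
MISSING = -1

#: Default upper bound of the repeat-count lattice.
DEFAULT_REPEAT_CAP = 35


class GenePopParseError(ValueError):
    """Raised when a GenePop file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus and its repeat-count lattice.

    Parameters
    ----------
    name:
        Locus label (e.g. ``"D14S306"``).
    motif_length:
        Repeat-motif length in bases (2 for dinucleotide, 4 for
        tetranucleotide loci).
    repeat_min, repeat_max:
        Inclusive bounds of the allele lattice, in repeat units.
    code_offset:
        Allele code-to-repeat mapping: ``repeat = code - code_offset``.
    """

    name: str
    motif_length: int = 2
    repeat_min: int = 1
    repeat_max: int = DEFAULT_REPEAT_CAP
    code_offset: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")
        if not self.repeat_min < self.repeat_max:
            raise ValueError(
                f"{self.name}: repeat_min ({self.repeat_min}) must be < "
                f"repeat_max ({self.repeat_max})"
            )

    @property
    def n_states(self) -> int:
        return self.repeat_max - self.repeat_min + 1


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid repeat-count calls with group labels.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; a missing genotype is
    ``(MISSING, MISSING)``.  Calls are unordered pairs and are stored sorted,
    so two matrices with the same genotypes compare equal regardless of the
    allele order in the source file.
    """

    ids: list[str]
    groups: list[str]
    loci: list[Locus]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        if len(self.groups) != len(self.ids):
            raise ValueError("groups and ids must have equal length")
        # normalize: unordered pairs stored sorted; a half-missing call is missing
        half_missing = (self.calls == MISSING).any(axis=2)
        self.calls = np.sort(self.calls, axis=2)
        self.calls[half_missing] = MISSING
        self._validate_lattice()

    def _validate_lattice(self) -> None:
        for j, locus in enumerate(self.loci):
            obs = self.calls[:, j, :]
            obs = obs[obs != MISSING]
            if obs.size and (obs.min() < locus.repeat_min or obs.max() > locus.repeat_max):
                raise ValueError(
                    f"locus {locus.name}: allele outside lattice "
                    f"[{locus.repeat_min}, {locus.repeat_max}]: "
                    f"range observed [{obs.min()}, {obs.max()}]"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)

    def locus_index(self, locus: Locus | str) -> int:
        name = locus.name if isinstance(locus, Locus) else locus
        for j, loc in enumerate(self.loci):
            if loc.name == name:
                return j
        raise KeyError(f"locus {name!r} not in matrix")

    def locus_calls(self, locus: Locus | str) -> np.ndarray:
        """Calls at one locus, shape (n_individuals, 2)."""
        return self.calls[:, self.locus_index(locus), :]

    def genotyped_mask(self, locus: Locus | str) -> np.ndarray:
        """Boolean mask of individuals with a non-missing call at `locus`."""
        return (self.locus_calls(locus) != MISSING).all(axis=1)

    def n_genotyped(self, locus: Locus | str) -> int:
        return int(self.genotyped_mask(locus).sum())

    def gene_copies(self, locus: Locus | str) -> np.ndarray:
        """Flat array of the non-missing gene copies at `locus` (length 2N)."""
        calls = self.locus_calls(locus)
        return calls[self.genotyped_mask(locus)].ravel()

    def subset_groups(self, keep: list[str]) -> "GenotypeMatrix":
        mask = [g in keep for g in self.groups]
        return GenotypeMatrix(
            ids=[i for i, m in zip(self.ids, mask) if m],
            groups=[g for g, m in zip(self.groups, mask) if m],
            loci=list(self.loci),
            calls=self.calls[np.asarray(mask, bool)].copy(),
        )

    def drop_loci(self, names: list[str]) -> "GenotypeMatrix":
        keep = [j for j, loc in enumerate(self.loci) if loc.name not in names]
        return GenotypeMatrix(
            ids=list(self.ids),
            groups=list(self.groups),
            loci=[self.loci[j] for j in keep],
            calls=self.calls[:, keep, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.groups == other.groups
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    # -- I/O ---------------------------------------------------------------

    def to_genepop(self, path, title: str = "msatdemog export") -> None:
        """Write in GenePop 4.x dialect (3-digit allele codes, 0 = missing)."""
        lines = [title]
        lines.extend(loc.name for loc in self.loci)
        order = {}
        for i, g in enumerate(self.groups):
            order.setdefault(g, []).append(i)
        for g, rows in order.items():
            lines.append("POP")
            for i in rows:
                codes = []
                for j, loc in enumerate(self.loci):
                    a, b = self.calls[i, j]
                    ca = 0 if a == MISSING else a + loc.code_offset
                    cb = 0 if b == MISSING else b + loc.code_offset
                    codes.append(f"{ca:03d}{cb:03d}")
                lines.append(f"{self.ids[i]} ,  " + " ".join(codes))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def to_csv(self, path) -> None:
        """CSV dialect: one row per individual, columns id,group,<locus>_1,<locus>_2."""
        data: dict[str, list] = {"id": self.ids, "group": self.groups}
        for j, loc in enumerate(self.loci):
            for k in (0, 1):
                col = self.calls[:, j, k]
                data[f"{loc.name}_{k + 1}"] = [
                    "" if v == MISSING else int(v) for v in col
                ]
        pd.DataFrame(data).to_csv(path, index=False)


def read_genepop(path, loci: list[Locus] | None = None) -> GenotypeMatrix:
    """Read a GenePop 4.x file (title line, locus names, POP blocks).

    Allele codes (2- or 3-digit) are mapped to repeat counts through each
    locus's ``code_offset``; code 0 is missing.  POP blocks become groups
    named ``pop1``, ``pop2``, ... unless group names can be inferred.

    Parameters
    ----------
    loci:
        Optional locus definitions (lattice bounds, code offsets).  Defaults
        to identity mapping on the default lattice.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise GenePopParseError("empty file")
    locus_names: list[str] = []
    i = 1
    while i < len(raw) and raw[i].strip().upper() != "POP":
        line = raw[i].strip()
        if line:
            # locus names may be comma-separated on one line
            locus_names.extend(n.strip() for n in line.split(",") if n.strip())
        i += 1
    if not locus_names:
        raise GenePopParseError(f"no locus names before first POP (line {i + 1})")
    if loci is None:
        loci = [Locus(name=n) for n in locus_names]
    else:
        by_name = {l.name: l for l in loci}
        missing_defs = [n for n in locus_names if n not in by_name]
        if missing_defs:
            raise GenePopParseError(f"no Locus definition for {missing_defs}")
        loci = [by_name[n] for n in locus_names]

    ids: list[str] = []
    groups: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    pop_empty = False
    while i < len(raw):
        line = raw[i].strip()
        if line.upper() == "POP":
            if pop_idx and pop_empty:
                logger.warning("empty POP block %d", pop_idx)
                warnings.warn(f"empty POP block {pop_idx}", stacklevel=2)
            pop_idx += 1
            pop_empty = True
            i += 1
            continue
        if not line:
            i += 1
            continue
        if "," not in line:
            raise GenePopParseError(f"line {i + 1}: expected 'id , codes', got {line!r}")
        pop_empty = False
        ind_id, _, code_part = line.partition(",")
        tokens = code_part.split()
        if len(tokens) != len(loci):
            raise GenePopParseError(
                f"line {i + 1}: {len(tokens)} genotype fields for {len(loci)} loci"
            )
        row = []
        for tok, loc in zip(tokens, loci):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenePopParseError(
                    f"line {i + 1}: bad genotype code {tok!r} at locus {loc.name}"
                )
            w = len(tok) // 2
            ca, cb = int(tok[:w]), int(tok[w:])
            a = MISSING if ca == 0 else ca - loc.code_offset
            b = MISSING if cb == 0 else cb - loc.code_offset
            row.append((a, b))
        ids.append(ind_id.strip())
        groups.append(f"pop{pop_idx}")
        rows.append(row)
        i += 1
    if pop_idx and pop_empty and rows:
        logger.warning("empty trailing POP block %d", pop_idx)
        warnings.warn(f"empty POP block {pop_idx}", stacklevel=2)

    calls = np.full((len(ids), len(loci), 2), MISSING, dtype=np.int64)
    for r, row in enumerate(rows):
        for j, (a, b) in enumerate(row):
            calls[r, j] = (a, b)
    return GenotypeMatrix(ids=ids, groups=groups, loci=loci, calls=calls)


def read_csv(path, loci: list[Locus] | None = None) -> GenotypeMatrix:
    """Read the package CSV dialect (columns ``id,group,<locus>_1,<locus>_2``)."""
    df = pd.read_csv(path, dtype={"id": str, "group": str})
    locus_names = []
    for col in df.columns:
        if col.endswith("_1"):
            locus_names.append(col[:-2])
    if loci is None:
        loci = [Locus(name=n) for n in locus_names]
    calls = np.full((len(df), len(loci), 2), MISSING, dtype=np.int64)
    for j, loc in enumerate(loci):
        for k in (0, 1):
            col = df[f"{loc.name}_{k + 1}"]
            vals = pd.to_numeric(col, errors="coerce")
            ok = vals.notna()
            calls[ok.to_numpy(), j, k] = vals[ok].astype(np.int64).to_numpy()
    return GenotypeMatrix(
        ids=df["id"].tolist(), groups=df["group"].tolist(), loci=loci, calls=calls
    )


def allele_frequencies(g: GenotypeMatrix, locus: Locus | str) -> pd.Series:
    """Allele frequencies at one locus from the 2N non-missing gene copies.

    Returns a Series indexed by repeat count, summing to 1.
    """
    copies = g.gene_copies(locus)
    if copies.size == 0:
        name = locus.name if isinstance(locus, Locus) else locus
        raise ValueError(f"locus {name}: all calls missing")
    alleles, counts = np.unique(copies, return_counts=True)
    return pd.Series(counts / copies.size, index=alleles, name="frequency")


# -- QC ---------------------------------------------------------------------


@dataclass
class LocusQC:
    """Per-locus null-allele screen result."""

    name: str
    assessable: bool
    null_freq: float = float("nan")
    p_homozygote_excess: float = float("nan")
    flagged: bool = False
    exclude: bool = False


@dataclass
class QCReport:
    """Null-allele / homozygote-excess screen over all loci."""

    loci: list[LocusQC] = field(default_factory=list)

    @property
    def excluded(self) -> list[str]:
        return [l.name for l in self.loci if l.exclude]

    def apply(self, g: GenotypeMatrix) -> GenotypeMatrix:
        """Return `g` without the loci recommended for exclusion."""
        return g.drop_loci(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(l) for l in self.loci])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([vars(l) for l in self.loci], fh, indent=2)


def _null_allele_estimate(g: GenotypeMatrix, locus: Locus) -> tuple[float, float]:
    """(null frequency estimate, observed heterozygote proportion).

    Estimator: (H_e - H_o) / (1 + H_e) with H_e the plain gene diversity
    1 - sum p_i^2 (no small-sample correction), the closed form used when a
    homozygote excess is attributed to a single segregating null allele.
    """
    calls = g.locus_calls(locus)[g.genotyped_mask(locus)]
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    freqs = allele_frequencies(g, locus).to_numpy()
    he = 1.0 - float(np.sum(freqs**2))
    return (he - ho) / (1.0 + he), ho


def screen_null_alleles(
    g: GenotypeMatrix,
    n_perm: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> QCReport:
    """Screen every locus for null alleles / scoring-driven homozygote excess.

    For each polymorphic locus the null-allele frequency is estimated as
    ``(H_e - H_o) / (1 + H_e)`` and a one-sided randomization test of
    homozygote excess is run by re-pairing the observed gene copies at
    random (Hardy-Weinberg null).  Loci significant after a sequential
    Bonferroni (Holm) correction are flagged and recommended for exclusion.
    Monomorphic loci are reported as not assessable.
    """
    from .sumstats import sequential_bonferroni

    rng = np.random.default_rng() if rng is None else rng
    results: list[LocusQC] = []
    pvals: list[float] = []
    testable: list[int] = []
    for idx, locus in enumerate(g.loci):
        copies = g.gene_copies(locus)
        if copies.size == 0 or np.unique(copies).size < 2:
            results.append(LocusQC(name=locus.name, assessable=False))
            continue
        est, ho_obs = _null_allele_estimate(g, locus)
        n_pairs = copies.size // 2
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(copies)
            pairs = perm[: 2 * n_pairs].reshape(n_pairs, 2)
            ho_perm = float((pairs[:, 0] != pairs[:, 1]).mean())
            if ho_perm <= ho_obs:  # as much homozygote excess as observed
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        results.append(
            LocusQC(name=locus.name, assessable=True, null_freq=est,
                    p_homozygote_excess=p)
        )
        pvals.append(p)
        testable.append(len(results) - 1)
    flags = sequential_bonferroni(pvals, alpha=alpha)
    for i, flag in zip(testable, flags):
        results[i].flagged = bool(flag)
        results[i].exclude = bool(flag)
    return QCReport(loci=results)
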