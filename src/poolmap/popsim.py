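"""In-silico F2 population simulator for bulked-segregant mapping studies.

Simulates an A x B cross between two fully homozygous parents: recombinant
egg and pollen haplotypes with a controlled genome-wide crossover count,
random gamete pairing into F2 genotypes, a multi-locus trait with one
dominant epistatic suppressor and several recessive direct-effect loci,
phenotype-extreme pool selection, and pooled short-read allele sampling at
each marker.

Genotypes are coded as the dosage of the parent-B allele: 0 = AA, 1 = AB,
2 = BB.  Haplotypes are coded per marker as 0 (parent A) / 1 (parent B).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSet",
    "TraitLocus",
    "TraitArchitecture",
    "F2Population",
    "PoolSample",
    "PoolSelectionError",
    "default_marker_set",
    "default_architecture",
    "simulate_gametes",
    "make_f2_population",
    "assign_phenotypes",
    "select_pools",
    "simulate_pool_reads",
    "parent_haplotypes",
]

GENO_AA, GENO_AB, GENO_BB = 0, 1, 2

#: column layout of the long-format allele-depth table shared with qtlseq/io
DEPTH_COLUMNS = ("chrom", "pos", "pool", "count_a", "count_b")


class PoolSelectionError(ValueError):
    """Raised when a phenotype class has fewer qualifying individuals than
    the requested pool size."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSet:
    """Ordered biallelic SNP map over a set of chromosomes.

    Parameters
    ----------
    chromosomes
        List of ``(name, length_bp)`` pairs defining the genome.
    markers
        DataFrame with columns ``chrom, pos, allele_a, allele_b``; positions
        are 1-based and strictly increasing within each chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    markers: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        chrom_names = [c for c, _ in self.chromosomes]
        if len(set(chrom_names)) != len(chrom_names):
            raise ValueError("duplicate chromosome names")
        unknown = set(self.markers["chrom"]) - set(chrom_names)
        if unknown:
            raise ValueError(f"markers on unknown chromosomes: {sorted(unknown)}")
        for name, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {name}")
        if (self.markers["allele_a"] == self.markers["allele_b"]).any():
            raise ValueError("allele_a == allele_b at some marker")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_length(self, name: str) -> int:
        for c, ln in self.chromosomes:
            if c == name:
                return ln
        raise KeyError(name)

    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def marker_index(self, chrom: str, pos: int) -> int:
        """Row index of the marker at (chrom, pos); KeyError if absent."""
        hit = self.markers.index[
            (self.markers["chrom"] == chrom) & (self.markers["pos"] == pos)
        ]
        if len(hit) == 0:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return int(hit[0])


@dataclass(frozen=True)
class TraitLocus:
    chromosome: str
    position: int
    mode: Literal["recessive_direct", "dominant_suppressor"]
    effect: float
    causal_parent: Literal["A", "B"]

    def __post_init__(self):
        if self.mode == "recessive_direct" and not self.effect > 0:
            raise ValueError("recessive_direct locus requires effect > 0")
        if self.mode == "dominant_suppressor" and self.effect != 0:
            raise ValueError("dominant_suppressor locus must have effect 0")


@dataclass(frozen=True)
class TraitArchitecture:
    loci: tuple[TraitLocus, ...]

    def __post_init__(self):
        direct = [l for l in self.loci if l.mode == "recessive_direct"]
        if direct and abs(sum(l.effect for l in direct) - 1.0) > 1e-9:
            raise ValueError("direct-locus effects must sum to 1.0")

    @property
    def suppressors(self) -> tuple[TraitLocus, ...]:
        return tuple(l for l in self.loci if l.mode == "dominant_suppressor")

    @property
    def direct_loci(self) -> tuple[TraitLocus, ...]:
        return tuple(l for l in self.loci if l.mode == "recessive_direct")


@dataclass
class F2Population:
    """F2 genotype matrix plus optional phenotypes.

    ``genotypes`` is (n_individuals x n_markers) uint8 of parent-B dosage.
    ``gamete_crossovers`` keeps the (egg, pollen) breakpoint records of every
    individual for testing.
    """

    marker_set: MarkerSet
    genotypes: np.ndarray
    phenotypes: np.ndarray | None = None
    gamete_crossovers: list[tuple[list, list]] | None = None

    def __post_init__(self):
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if self.genotypes.shape[1] != self.marker_set.n_markers:
            raise ValueError("genotype matrix width != number of markers")
        if self.phenotypes is not None:
            p = np.asarray(self.phenotypes, dtype=float)
            if p.shape != (self.genotypes.shape[0],):
                raise ValueError("one phenotype per individual required")
            if ((p < 0) | (p > 1)).any():
                raise ValueError("phenotypes must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]


@dataclass(frozen=True)
class PoolSample:
    label: Literal["high", "low"]
    member_indices: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.member_indices)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_marker_set(
    n_chromosomes: int = 10,
    chrom_length: int = 30_000_000,
    markers_per_chrom: int = 5_000,
) -> MarkerSet:
    """Synthetic genome standing in for a dense parental SNP backbone.

    Ten 30-Mb chromosomes named ``A01``..``A10`` with uniformly spaced
    markers (every ``chrom_length // markers_per_chrom`` bp), so the
    chromosome midpoint is always a marker position.
    """
    names = [f"A{i + 1:02d}" for i in range(n_chromosomes)]
    spacing = chrom_length // markers_per_chrom
    pos = np.arange(1, markers_per_chrom + 1) * spacing
    frames = []
    # alternate the two parental alleles over a fixed nucleotide cycle
    cycle_a = np.array(list("ACGT"))
    cycle_b = np.array(list("GTAC"))
    for name in names:
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "allele_a": cycle_a[np.arange(markers_per_chrom) % 4],
                    "allele_b": cycle_b[np.arange(markers_per_chrom) % 4],
                }
            )
        )
    markers = pd.concat(frames, ignore_index=True)
    return MarkerSet(tuple((n, chrom_length) for n in names), markers)


def default_architecture(marker_set: MarkerSet) -> TraitArchitecture:
    """Six-locus architecture: a dominant suppressor (allele from the
    non-trait parent B) on chromosome 2, a 60% recessive direct locus on
    chromosome 4, and four 10% recessive direct loci on chromosomes 6-9,
    all at mid-chromosome marker positions."""
    names = [c for c, _ in marker_set.chromosomes]

    def mid(chrom: str) -> int:
        sub = marker_set.markers.loc[marker_set.markers["chrom"] == chrom, "pos"]
        target = marker_set.chrom_length(chrom) // 2
        return int(sub.iloc[(sub - target).abs().argmin()])

    loci = [
        TraitLocus(names[1], mid(names[1]), "dominant_suppressor", 0.0, "B"),
        TraitLocus(names[3], mid(names[3]), "recessive_direct", 0.6, "A"),
    ]
    for chrom in (names[5], names[6], names[7], names[8]):
        loci.append(TraitLocus(chrom, mid(chrom), "recessive_direct", 0.1, "A"))
    return TraitArchitecture(tuple(loci))


def parent_haplotypes(marker_set: MarkerSet, parent: str, n: int) -> np.ndarray:
    """n identical non-recombinant haplotypes of one parent (testing aid)."""
    val = {"A": 0, "B": 1}[parent]
    return np.full((n, marker_set.n_markers), val, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Gamete and population simulation
# ---------------------------------------------------------------------------

def simulate_gametes(
    marker_set: MarkerSet,
    n_gametes: int,
    mean_crossovers: float = 25,
    bias: float = 0.2,
    seed: int | None = None,
) -> tuple[np.ndarray, list[list[tuple[str, int]]]]:
    """Simulate recombinant F1 gametes over the marker map.

    Each gamete's genome-wide crossover count is drawn uniformly from the
    closed integer range ``[round(mean*(1-bias)), round(mean*(1+bias))]``.
    Crossovers are apportioned to chromosomes multinomially in proportion
    to chromosome length and placed uniformly; the starting parental phase
    of each chromosome is an independent fair coin (independent assortment).

    Returns
    -------
    haplotypes : (n_gametes, n_markers) uint8 array, 0 = parent A allele
    crossovers : per-gamete list of (chromosome, breakpoint_bp); a marker at
        position p lies downstream of a breakpoint x iff p > x
    """
    if marker_set.n_markers == 0:
        raise ValueError("marker_set is empty")
    if mean_crossovers < 0:
        raise ValueError("mean_crossovers must be >= 0")
    if not 0 <= bias < 1:
        raise ValueError("bias must satisfy 0 <= bias < 1")
    rng = np.random.default_rng(seed)

    lo = int(round(mean_crossovers * (1 - bias)))
    hi = int(round(mean_crossovers * (1 + bias)))
    counts = rng.integers(lo, hi + 1, size=n_gametes)

    chrom_names = [c for c, _ in marker_set.chromosomes]
    lengths = np.array([ln for _, ln in marker_set.chromosomes], dtype=float)
    probs = lengths / lengths.sum()

    # marker positions grouped by chromosome, preserving global column order
    by_chrom = {
        name: (
            marker_set.markers.index[marker_set.markers["chrom"] == name].to_numpy(),
            marker_set.markers.loc[marker_set.markers["chrom"] == name, "pos"].to_numpy(),
        )
        for name in chrom_names
    }

    haplotypes = np.empty((n_gametes, marker_set.n_markers), dtype=np.uint8)
    records: list[list[tuple[str, int]]] = []
    per_chrom = rng.multinomial(counts, probs)  # (n_gametes, n_chrom)
    phases = rng.integers(0, 2, size=(n_gametes, len(chrom_names)))
    for g in range(n_gametes):
        rec: list[tuple[str, int]] = []
        for ci, name in enumerate(chrom_names):
            cols, pos = by_chrom[name]
            k = per_chrom[g, ci]
            breaks = np.sort(rng.integers(1, int(lengths[ci]) + 1, size=k))
            n_before = np.searchsorted(breaks, pos, side="left")
            haplotypes[g, cols] = (phases[g, ci] + n_before) % 2
            rec.extend((name, int(b)) for b in breaks)
        records.append(rec)
    return haplotypes, records


def make_f2_population(
    marker_set: MarkerSet,
    egg_haplotypes: np.ndarray,
    pollen_haplotypes: np.ndarray,
    seed: int | None = None,
    egg_crossovers: Sequence | None = None,
    pollen_crossovers: Sequence | None = None,
) -> F2Population:
    """Pair egg with pollen haplotypes into F2 genotypes (selfed F1).

    Pairing is uniform without replacement: both haplotype sets are
    independently permuted and paired row-wise, producing
    ``min(n_eggs, n_pollen)`` individuals.  Genotype is the unordered allele
    pair, stored as parent-B dosage.
    """
    eggs = np.asarray(egg_haplotypes, dtype=np.uint8)
    pollen = np.asarray(pollen_haplotypes, dtype=np.uint8)
    if eggs.ndim != 2 or pollen.ndim != 2:
        raise ValueError("haplotype arrays must be 2-D")
    if eggs.shape[1] != pollen.shape[1] or eggs.shape[1] != marker_set.n_markers:
        raise ValueError("haplotype marker dimension mismatch with marker set")
    if eggs.shape[0] == 0 or pollen.shape[0] == 0:
        raise ValueError("need at least one haplotype of each type")
    rng = np.random.default_rng(seed)
    n = min(eggs.shape[0], pollen.shape[0])
    ei = rng.permutation(eggs.shape[0])[:n]
    pi = rng.permutation(pollen.shape[0])[:n]
    genotypes = eggs[ei] + pollen[pi]
    crossovers = None
    if egg_crossovers is not None and pollen_crossovers is not None:
        crossovers = [(egg_crossovers[e], pollen_crossovers[p]) for e, p in zip(ei, pi)]
    return F2Population(marker_set, genotypes, gamete_crossovers=crossovers)


def assign_phenotypes(pop: F2Population, arch: TraitArchitecture) -> F2Population:
    """Score the multi-locus trait on every individual.

    An individual carrying at least one suppressor allele at any
    dominant-suppressor locus has phenotype 0 (dominant epistasis over all
    direct loci).  Otherwise the phenotype is the sum of effects of the
    recessive direct loci at which the individual is homozygous for the
    causal parent's allele.
    """
    cols = {}
    for locus in arch.loci:
        cols[locus] = pop.marker_set.marker_index(locus.chromosome, locus.position)
    n = pop.n_individuals
    pheno = np.zeros(n, dtype=float)
    suppressed = np.zeros(n, dtype=bool)
    for locus in arch.suppressors:
        dosage_b = pop.genotypes[:, cols[locus]]
        carrier = dosage_b >= 1 if locus.causal_parent == "B" else dosage_b <= 1
        suppressed |= carrier
    for locus in arch.direct_loci:
        dosage_b = pop.genotypes[:, cols[locus]]
        homo_causal = dosage_b == (0 if locus.causal_parent == "A" else 2)
        pheno += locus.effect * homo_causal
    pheno[suppressed] = 0.0
    # effects are decimal fractions; round away float-sum residue so the
    # parental anchor is exactly 1.0 and phenotype classes compare exactly
    return replace(pop, phenotypes=np.round(pheno, 12))


def select_pools(
    phenotypes: np.ndarray,
    high_threshold: float = 0.7,
    low_value: float = 0.0,
    pool_size: int = 25,
    seed: int | None = None,
) -> tuple[PoolSample, PoolSample]:
    """Draw the two phenotype-extreme pools.

    The high pool is ``pool_size`` individuals sampled uniformly from those
    with phenotype strictly greater than ``high_threshold``; the low pool
    from those with phenotype exactly ``low_value``.  The two candidate sets
    are disjoint by construction whenever ``low_value <= high_threshold``.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    phen = np.asarray(phenotypes, dtype=float)
    rng = np.random.default_rng(seed)
    high_cand = np.flatnonzero(phen > high_threshold)
    low_cand = np.flatnonzero(phen == low_value)
    if len(high_cand) < pool_size:
        raise PoolSelectionError(
            f"high pool: only {len(high_cand)} individuals with phenotype > "
            f"{high_threshold}, need {pool_size}"
        )
    if len(low_cand) < pool_size:
        raise PoolSelectionError(
            f"low pool: only {len(low_cand)} individuals with phenotype == "
            f"{low_value}, need {pool_size}"
        )
    high = rng.choice(high_cand, size=pool_size, replace=False)
    low = rng.choice(low_cand, size=pool_size, replace=False)
    return (
        PoolSample("high", tuple(int(i) for i in np.sort(high))),
        PoolSample("low", tuple(int(i) for i in np.sort(low))),
    )


def simulate_pool_reads(
    pop: F2Population,
    pool: PoolSample,
    depth: int = 30,
    error_rate: float = 0.01,
    seed: int | None = None,
    poisson_depth: bool = False,
) -> pd.DataFrame:
    """Sample pooled short reads at every marker for one pool.

    Each read picks a pool member uniformly, then one of its two alleles
    uniformly, then flips allele with probability ``error_rate``.  Reads are
    conditionally independent given the pool's genotypes, so the allele
    counts at a marker are drawn binomially at the exact per-marker
    probability.  By default every marker receives exactly ``depth`` reads;
    with ``poisson_depth`` the per-marker total is Poisson(depth).

    Returns a long-format DataFrame with columns
    ``chrom, pos, pool, count_a, count_b``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must satisfy 0 <= error_rate < 0.5")
    if pool.size == 0:
        raise ValueError("empty pool")
    rng = np.random.default_rng(seed)
    members = pop.genotypes[list(pool.member_indices)]
    q = members.mean(axis=0) / 2.0  # true parent-B allele frequency per marker
    p_b = q * (1 - error_rate) + (1 - q) * error_rate
    m = pop.marker_set.n_markers
    totals = rng.poisson(depth, size=m) if poisson_depth else np.full(m, depth)
    count_b = rng.binomial(totals, p_b)
    return pd.DataFrame(
        {
            "chrom": pop.marker_set.markers["chrom"].to_numpy(),
            "pos": pop.marker_set.markers["pos"].to_numpy(),
            "pool": pool.label,
            "count_a": totals - count_b,
            "count_b": count_b,
        }
    )
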