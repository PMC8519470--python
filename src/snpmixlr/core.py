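"""Core domain types and the genotype-permutation engine for biallelic mixtures.

A biallelic SNP locus in a forensic mixture carries at most two alleles.  After
per-locus relabeling ("a" = the allele with the larger read count, "b" = the
other), every locus of a typing protocol is described by the same small
vocabulary: read counts ``Q_a >= Q_b``, population frequencies ``f_a``/``f_b``,
and the three genotypes AA, AB, BB with Hardy-Weinberg probabilities
``f_a**2``, ``2*f_a*f_b``, ``f_b**2``.

An n-person mixture showing both alleles (biallelic evidence, E{a;b}) is
explained by the set of *ordered* genotype assignments over the n contributors
that jointly carry both alleles — every tuple in {AA,AB,BB}^n except the
all-AA and all-BB ones, hence ``3**n - 2`` permutation states (7 for two
contributors, 25 for three, 79 for four, ...).  Conditioning on persons of
interest (POIs) pins the leading columns of the matrix to the POI genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from functools import lru_cache
from itertools import product
from typing import Mapping, Sequence

__all__ = [
    "DEFAULT_TAU",
    "MAX_CONTRIBUTORS",
    "Genotype",
    "EvidenceClass",
    "CombinationClass",
    "LocusFrequencies",
    "LocusEvidence",
    "ReferenceProfile",
    "PermutationState",
    "PermutationMatrix",
    "relabel_alleles",
    "classify_evidence",
    "enumerate_permutations",
    "condition_on_pois",
    "classify_combination",
    "genotype_counts",
]

#: Default dynamic threshold for calling the minor allele: the evidence is
#: biallelic iff the minor read is >= tau times the major read.
DEFAULT_TAU = 0.05

#: Largest supported number of contributors; the matrix has 3**n - 2 states.
MAX_CONTRIBUTORS = 8


class Genotype(IntEnum):
    """A biallelic genotype in the per-locus a/b labeling.

    The integer values fix the canonical enumeration order AA < AB < BB.
    """

    AA = 0
    AB = 1
    BB = 2

    @property
    def dose_a(self) -> int:
        """Number of 'a' allele copies carried (2, 1 or 0)."""
        return 2 - int(self)

    @property
    def dose_b(self) -> int:
        """Number of 'b' allele copies carried (0, 1 or 2)."""
        return int(self)

    def frequency(self, f_a: float, f_b: float) -> float:
        """Hardy-Weinberg population frequency of this genotype."""
        if self is Genotype.AA:
            return f_a * f_a
        if self is Genotype.BB:
            return f_b * f_b
        return 2.0 * f_a * f_b


class EvidenceClass(Enum):
    """Allelic pattern of the locus evidence after thresholding."""

    BIALLELIC = "biallelic"      # E{a;b}: both alleles called
    MONOALLELIC = "monoallelic"  # E{a}: minor read below the dynamic threshold


class CombinationClass(Enum):
    """The five parsimonious genotype-combination classes of a biallelic state.

    Every permutation state producing biallelic evidence falls in exactly one
    of these, whatever the number of contributors.
    """

    R_AA_S_BB = "rAA+sBB"
    R_AA_S_AB = "rAA+sAB"
    R_AA_S_AB_T_BB = "rAA+sAB+tBB"
    R_AB_S_BB = "rAB+sBB"
    N_AB = "nAB"


@dataclass(frozen=True)
class LocusFrequencies:
    """Population frequencies of the two alleles at one locus, a/b labeled.

    ``allele_a`` is the name of the major-*read* allele of the matching
    evidence record (not necessarily the population-major allele).
    """

    locus_id: str
    allele_a: str
    allele_b: str
    f_a: float
    f_b: float

    def __post_init__(self) -> None:
        if not (self.f_a > 0.0 and self.f_b > 0.0):
            raise ValueError(
                f"{self.locus_id}: allele frequencies must be positive, "
                f"got f_a={self.f_a}, f_b={self.f_b}"
            )
        if abs(self.f_a + self.f_b - 1.0) > 1e-9:
            raise ValueError(
                f"{self.locus_id}: allele frequencies must sum to 1, "
                f"got {self.f_a} + {self.f_b} = {self.f_a + self.f_b}"
            )

    def genotype_frequency(self, genotype: Genotype) -> float:
        return genotype.frequency(self.f_a, self.f_b)


@dataclass(frozen=True)
class LocusEvidence:
    """Read counts for the two alleles at one locus, a/b labeled.

    ``q_a`` is the major read, ``q_b`` the minor read; the invariant
    ``q_a >= q_b >= 0`` is enforced.  A locus with ``q_a == 0`` carries no
    usable evidence and is excluded from likelihood products downstream.
    """

    locus_id: str
    q_a: int
    q_b: int
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.q_b < 0 or self.q_a < self.q_b:
            raise ValueError(
                f"{self.locus_id}: need Q_a >= Q_b >= 0, "
                f"got Q_a={self.q_a}, Q_b={self.q_b}"
            )
        if not (0.0 < self.tau < 1.0):
            raise ValueError(f"{self.locus_id}: tau must be in (0,1), got {self.tau}")

    @property
    def usable(self) -> bool:
        return self.q_a > 0

    @property
    def total(self) -> int:
        return self.q_a + self.q_b

    @property
    def evidence_class(self) -> EvidenceClass:
        return classify_evidence(self.q_a, self.q_b, self.tau)


def classify_evidence(q_a: int, q_b: int, tau: float = DEFAULT_TAU) -> EvidenceClass:
    """Call the locus evidence biallelic or monoallelic.

    The minor allele is called (biallelic evidence E{a;b}) whenever its read
    count is greater than or equal to the major read multiplied by ``tau``;
    below that dynamic threshold the evidence is monoallelic E{a}, interpreted
    downstream as biallelic evidence whose minor allele dropped out.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must be in (0,1), got {tau}")
    if q_a <= 0:
        raise ValueError("classify_evidence requires Q_a > 0")
    if q_b >= tau * q_a:
        return EvidenceClass.BIALLELIC
    return EvidenceClass.MONOALLELIC


class UnusableLocusError(ValueError):
    """Raised when a locus has no reads at all and cannot be interpreted."""


def relabel_alleles(
    locus_id: str,
    raw_reads: Mapping[str, int],
    raw_freqs: Mapping[str, float],
    tau: float = DEFAULT_TAU,
) -> tuple[LocusEvidence, LocusFrequencies]:
    """Relabel a locus so that "a" is the allele with the larger read count.

    Replaces the population wildtype/mutant (major/minor frequency)
    nomenclature with a per-evidence major/minor *read* nomenclature; the
    population frequencies are carried along under the new labels.  Ties
    (``Q_a == Q_b``) are broken deterministically by taking the
    lexicographically smaller allele name as "a".

    Raises ``ValueError`` if the locus does not have exactly two alleles and
    ``UnusableLocusError`` if both read counts are zero.
    """
    if set(raw_reads) != set(raw_freqs) or len(raw_reads) != 2:
        raise ValueError(
            f"{locus_id}: expected the same two allele names in reads and "
            f"frequencies, got reads={sorted(raw_reads)} freqs={sorted(raw_freqs)}"
        )
    for name, count in raw_reads.items():
        if count < 0:
            raise ValueError(f"{locus_id}: negative read count for allele {name}")
    # Sort by (-reads, name): major reads first, lexicographic tie-break.
    (name_a, name_b) = sorted(raw_reads, key=lambda k: (-raw_reads[k], k))
    if raw_reads[name_a] == 0:
        raise UnusableLocusError(f"{locus_id}: no reads for either allele")
    ev = LocusEvidence(locus_id, raw_reads[name_a], raw_reads[name_b], tau=tau)
    fr = LocusFrequencies(locus_id, name_a, name_b, raw_freqs[name_a], raw_freqs[name_b])
    return ev, fr


@dataclass
class ReferenceProfile:
    """A typed reference individual: locus id -> (allele, allele) in original names.

    Homozygotes repeat the allele name.  Genotypes are converted to the
    per-locus AA/AB/BB codes against a locus's a/b allele map, so the same
    profile is portable across evidence files that flip major/minor.
    """

    sample_id: str
    genotypes: dict[str, tuple[str, str]] = field(default_factory=dict)

    def resolve(self, freqs: LocusFrequencies) -> Genotype:
        """Express this profile's genotype at a locus in the locus's a/b codes.

        Raises ``KeyError`` if the profile lacks the locus and ``ValueError``
        if either named allele is not one of the locus's two alleles.
        """
        alleles = self.genotypes[freqs.locus_id]
        dose_a = 0
        for allele in alleles:
            if allele == freqs.allele_a:
                dose_a += 1
            elif allele != freqs.allele_b:
                raise ValueError(
                    f"profile {self.sample_id}, locus {freqs.locus_id}: allele "
                    f"{allele!r} is neither {freqs.allele_a!r} nor {freqs.allele_b!r}"
                )
        return Genotype(2 - dose_a)


@dataclass(frozen=True)
class PermutationState:
    """One ordered assignment of genotypes to the n contributors."""

    genotypes: tuple[Genotype, ...]

    @property
    def n(self) -> int:
        return len(self.genotypes)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(number of AA, number of AB, number of BB) in the state."""
        return genotype_counts(self.genotypes)

    @property
    def combination_class(self) -> CombinationClass:
        return classify_combination(self.genotypes)

    @property
    def fully_redundant(self) -> bool:
        """True if every contributor carries the identical genotype."""
        return len(set(self.genotypes)) == 1


@dataclass(frozen=True)
class PermutationMatrix:
    """All permutation states explaining biallelic evidence for n contributors."""

    n: int
    states: tuple[PermutationState, ...]
    conditioned_on: tuple[tuple[int, Genotype], ...] = ()


def genotype_counts(genotypes: Sequence[Genotype]) -> tuple[int, int, int]:
    """Multiplicities (r, s, t) of AA, AB, BB in an ordered genotype tuple."""
    n_aa = n_ab = n_bb = 0
    for g in genotypes:
        if g is Genotype.AA:
            n_aa += 1
        elif g is Genotype.AB:
            n_ab += 1
        else:
            n_bb += 1
    return n_aa, n_ab, n_bb


@lru_cache(maxsize=None)
def _enumerate(n: int) -> tuple[PermutationState, ...]:
    all_aa = (Genotype.AA,) * n
    all_bb = (Genotype.BB,) * n
    return tuple(
        PermutationState(g)
        for g in product((Genotype.AA, Genotype.AB, Genotype.BB), repeat=n)
        if g != all_aa and g != all_bb
    )


def enumerate_permutations(n: int, max_n: int = MAX_CONTRIBUTORS) -> PermutationMatrix:
    """Build the unconditioned permutation matrix for n contributors.

    States are all ordered tuples over {AA, AB, BB} except the two monoallelic
    ones (all-AA, all-BB), in lexicographic order of the canonical genotype
    order AA < AB < BB; there are ``3**n - 2`` of them.
    """
    if n < 1:
        raise ValueError(f"number of contributors must be >= 1, got {n}")
    if n > max_n:
        raise ValueError(f"n={n} exceeds the configured maximum {max_n}")
    return PermutationMatrix(n=n, states=_enumerate(n))


def condition_on_pois(
    matrix: PermutationMatrix, pois: Sequence[Genotype]
) -> PermutationMatrix:
    """Restrict a matrix to the states carrying the POI genotypes.

    The eta POI genotypes occupy the first eta columns in the given order;
    the remaining columns range freely.  Because unconditioned likelihood
    sums are symmetric under column permutation, pinning POIs to the leading
    columns is observationally equivalent to any other placement.
    """
    eta = len(pois)
    if eta > matrix.n:
        raise ValueError(f"{eta} POIs exceed the {matrix.n} hypothesized contributors")
    prefix = tuple(pois)
    states = tuple(s for s in matrix.states if s.genotypes[:eta] == prefix)
    return PermutationMatrix(
        n=matrix.n,
        states=states,
        conditioned_on=tuple(enumerate(prefix)),
    )


@lru_cache(maxsize=None)
def classify_combination(genotypes: tuple[Genotype, ...]) -> CombinationClass:
    """Assign a biallelic permutation state to its parsimonious class."""
    n_aa, n_ab, n_bb = genotype_counts(genotypes)
    if n_aa + n_ab + n_bb != len(genotypes):  # pragma: no cover - defensive
        raise AssertionError("genotype counts do not partition the state")
    if n_ab == 0:
        if n_aa == 0 or n_bb == 0:
            raise ValueError(
                f"state {genotypes} yields monoallelic evidence and is not "
                "part of the biallelic permutation matrix"
            )
        return CombinationClass.R_AA_S_BB
    if n_aa > 0 and n_bb > 0:
        return CombinationClass.R_AA_S_AB_T_BB
    if n_aa > 0:
        return CombinationClass.R_AA_S_AB
    if n_bb > 0:
        return CombinationClass.R_AB_S_BB
    return CombinationClass.N_AB
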