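"""Synthetic MPS read evidence for n-person biallelic SNP mixtures.

Emulates the kind of data a massively-parallel-sequencing identity panel
produces: a panel of biallelic loci with known population frequencies,
contributor genotypes drawn in Hardy-Weinberg proportions, and per-locus
allele read counts proportional to allele dose times mixing ratio, with
configurable sequencing depth, count overdispersion and a hard read floor
that zeroes weak minor-allele signals (simulated dropout).

All randomness flows from a single integer seed through a
``numpy.random.SeedSequence`` split (one child stream per stage), so any
sub-result is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import LocusEvidence, LocusFrequencies, ReferenceProfile, relabel_alleles

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedMixture",
    "make_freq_panel",
    "sample_profiles",
    "simulate_reads",
    "simulate_mixture",
]

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated mixture.

    Defaults mirror a typical forensic MPS SNP protocol: 133 common
    biallelic loci (minor allele frequency 0.2-0.5), two contributors in
    equal proportions, about a thousand reads per locus, modest
    overdispersion and no artificial dropout floor.
    """

    L: int = 133
    maf_range: tuple[float, float] = (0.2, 0.5)
    n: int = 2
    ratios: tuple[float, ...] = (1.0, 1.0)
    depth: float = 1000.0
    overdispersion: float = 0.0
    dropout_floor: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.L < 1:
            raise ValueError(f"need at least one locus, got L={self.L}")
        if self.n < 1:
            raise ValueError(f"need at least one contributor, got n={self.n}")
        if len(self.ratios) != self.n:
            raise ValueError(
                f"{len(self.ratios)} mixing weights for {self.n} contributors"
            )
        if any(r <= 0 for r in self.ratios):
            raise ValueError("mixing weights must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be nonnegative")

    @property
    def fractions(self) -> tuple[float, ...]:
        total = sum(self.ratios)
        return tuple(r / total for r in self.ratios)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated evidence table."""

    profiles: list[ReferenceProfile]
    fractions: tuple[float, ...]
    expected_doses: pd.DataFrame  # locus_id, allele1, allele2, dose1, dose2
    flagged_loci: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "contributors": [p.sample_id for p in self.profiles],
            "fractions": list(self.fractions),
            "flagged_loci": list(self.flagged_loci),
        }


@dataclass
class SimulatedMixture:
    """Panel + evidence + contributor profiles + ground truth, one bundle."""

    config: SimulationConfig
    panel: pd.DataFrame
    evidence: pd.DataFrame
    profiles: list[ReferenceProfile]
    truth: TruthRecord

    def dataset(self) -> list[tuple[LocusEvidence, LocusFrequencies]]:
        """Relabeled (evidence, frequencies) pairs ready for the LR engines."""
        return build_dataset(self.panel, self.evidence)


def make_freq_panel(
    L: int,
    maf_range: tuple[float, float] = (0.2, 0.5),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """A panel of L biallelic loci with minor frequencies uniform in maf_range.

    Columns: ``locus_id, allele1, allele2, freq1, freq2`` with allele1 the
    population-major allele — the evidence-driven a/b relabeling happens
    later, per evidence file.
    """
    if L < 1:
        raise ValueError(f"need at least one locus, got L={L}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    rng = np.random.default_rng() if rng is None else rng
    maf = rng.uniform(lo, hi, size=L)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=L)]
    return pd.DataFrame(
        {
            "locus_id": [f"rs{100000 + i}" for i in range(L)],
            "allele1": [p[0] for p in pairs],
            "allele2": [p[1] for p in pairs],
            "freq1": 1.0 - maf,
            "freq2": maf,
        }
    )


def sample_profiles(
    panel: pd.DataFrame,
    n: int,
    rng: np.random.Generator | None = None,
    prefix: str = "SIM",
) -> list[ReferenceProfile]:
    """Draw n reference profiles in Hardy-Weinberg proportions.

    At each locus a contributor is allele1-homozygous, heterozygous or
    allele2-homozygous with probabilities ``p**2, 2pq, q**2``; draws are
    independent across loci and contributors.
    """
    if len(panel) == 0:
        raise ValueError("cannot sample profiles from an empty panel")
    rng = np.random.default_rng() if rng is None else rng
    profiles = []
    p = panel["freq1"].to_numpy(float)
    probs = np.stack([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)], axis=1)
    for k in range(n):
        u = rng.random(len(panel))
        codes = (u >= probs[:, 0]).astype(int) + (u >= probs[:, 0] + probs[:, 1])
        genotypes = {}
        for row, code in zip(panel.itertuples(index=False), codes):
            if code == 0:
                genotypes[row.locus_id] = (row.allele1, row.allele1)
            elif code == 1:
                genotypes[row.locus_id] = (row.allele1, row.allele2)
            else:
                genotypes[row.locus_id] = (row.allele2, row.allele2)
        profiles.append(ReferenceProfile(f"{prefix}{k + 1}", genotypes))
    return profiles


def simulate_reads(
    panel: pd.DataFrame,
    profiles: Sequence[ReferenceProfile],
    ratios: Sequence[float],
    depth: float = 1000.0,
    overdispersion: float = 0.0,
    dropout_floor: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Realize per-locus allele read counts for a mixture of the profiles.

    The expected fraction of reads carrying an allele is the ratio-weighted
    mean of the contributors' allele doses (copies/2).  Counts are drawn
    from a mean-preserving gamma-Poisson family: with overdispersion 0 the
    counts are plain Poisson (multinomial thinning of the total depth);
    with overdispersion d > 0 each allele mean m is first jittered by a
    Gamma(1/d, d) factor, giving negative-binomial counts with variance
    ``m * (1 + d*m)``.  Realized counts below ``dropout_floor`` are zeroed
    (simulated dropout).  A locus realizing zero total reads is redrawn
    once, then flagged.
    """
    if len(profiles) != len(ratios):
        raise ValueError("one mixing weight per contributor is required")
    rng = np.random.default_rng() if rng is None else rng
    weights = np.asarray(ratios, float)
    weights = weights / weights.sum()

    rows = []
    dose_rows = []
    flagged = []
    for row in panel.itertuples(index=False):
        dose1 = 0.0
        for w, prof in zip(weights, profiles):
            alleles = prof.genotypes[row.locus_id]
            dose1 += w * sum(a == row.allele1 for a in alleles) / 2.0
        frac = np.array([dose1, 1.0 - dose1])
        means = depth * frac

        def draw() -> np.ndarray:
            m = means.copy()
            if overdispersion > 0:
                jitter = rng.gamma(1.0 / overdispersion, overdispersion, size=2)
                m = m * jitter
            return rng.poisson(np.clip(m, 0.0, None))

        reads = draw()
        if reads.sum() == 0:
            reads = draw()
            if reads.sum() == 0:
                flagged.append(row.locus_id)
        if dropout_floor > 0:
            reads = np.where(reads < dropout_floor, 0, reads)
        rows.append(
            {
                "locus_id": row.locus_id,
                "allele1": row.allele1,
                "allele2": row.allele2,
                "reads1": int(reads[0]),
                "reads2": int(reads[1]),
            }
        )
        dose_rows.append(
            {
                "locus_id": row.locus_id,
                "allele1": row.allele1,
                "allele2": row.allele2,
                "dose1": dose1,
                "dose2": 1.0 - dose1,
            }
        )
    evidence = pd.DataFrame(rows)
    truth = TruthRecord(
        profiles=list(profiles),
        fractions=tuple(weights.tolist()),
        expected_doses=pd.DataFrame(dose_rows),
        flagged_loci=flagged,
    )
    return evidence, truth


def simulate_mixture(config: SimulationConfig) -> SimulatedMixture:
    """One-stop simulation: panel, profiles, reads and truth from one seed."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    panel = make_freq_panel(
        config.L, config.maf_range, np.random.default_rng(children[0])
    )
    profiles = sample_profiles(panel, config.n, np.random.default_rng(children[1]))
    evidence, truth = simulate_reads(
        panel,
        profiles,
        config.ratios,
        depth=config.depth,
        overdispersion=config.overdispersion,
        dropout_floor=config.dropout_floor,
        rng=np.random.default_rng(children[2]),
    )
    return SimulatedMixture(config, panel, evidence, profiles, truth)


def build_dataset(
    panel: pd.DataFrame, evidence: pd.DataFrame, tau: float = 0.05
) -> list[tuple[LocusEvidence, LocusFrequencies]]:
    """Join a panel and an evidence table into relabeled engine inputs."""
    freq_by_locus = {
        r.locus_id: {r.allele1: float(r.freq1), r.allele2: float(r.freq2)}
        for r in panel.itertuples(index=False)
    }
    dataset = []
    for r in evidence.itertuples(index=False):
        if r.locus_id not in freq_by_locus:
            raise KeyError(f"evidence locus {r.locus_id} is absent from the panel")
        reads = {r.allele1: int(r.reads1), r.allele2: int(r.reads2)}
        if sum(reads.values()) == 0:
            continue
        dataset.append(relabel_alleles(r.locus_id, reads, freq_by_locus[r.locus_id], tau))
    return dataset
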