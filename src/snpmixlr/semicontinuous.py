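"""Semi-continuous likelihoods and likelihood ratios for biallelic mixtures.

The semi-continuous model scores a locus from allele presence/absence only,
plus a dropout term for loci where the minor allele fell below the calling
threshold.  Dropout probabilities are not calibrated by logistic regression;
instead the locus *h index* — the minor read divided by the major read — acts
as their proxy: h near 1 means a well-balanced biallelic record, h near 0 an
extreme imbalance in which the minor allele is considered dropped.

For biallelic evidence E{a;b} under n contributors and eta persons of
interest (POIs) the likelihoods follow from the binomial expansion
``(f_a + f_b)**(2n) = 1``:

=====================  =========================================
POI pattern            P(E{a;b} | ...)
=====================  =========================================
no POI                 ``1 - f_a**(2n) - f_b**(2n)``
POI(s) all AA          ``1 - f_a**(2(n-eta))``
POI(s) all BB          ``1 - f_b**(2(n-eta))``
POIs cover both        ``1``
=====================  =========================================

For monoallelic evidence E{a}, re-read as E{a;b_d} (the minor allele b
dropped out):

=====================  =========================================
POI pattern            P(E{a;b_d} | ...)
=====================  =========================================
POI(s) all AA          ``(1 - h) * f_a**(2(n-eta))``
any POI AB             ``h``
any POI BB             ``h**2 * f_b**(2(n-eta))``
=====================  =========================================

With several POIs the most constraining genotype (BB, then AB, then AA for
monoallelic evidence) selects the formula and the full eta is subtracted in
the exponent.  The mirror-image cells in which the *major* allele dropped
are provided for completeness but are unreachable while the canonical
``Q_a >= Q_b`` labeling holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .core import (
    EvidenceClass,
    Genotype,
    LocusEvidence,
    LocusFrequencies,
    ReferenceProfile,
)
from .report import PER_LOCUS_COLUMNS, LRReport

__all__ = [
    "Hypothesis",
    "LocusLikelihood",
    "h_index",
    "semicont_likelihood",
    "semicont_lr",
    "dropin_scan",
    "resolve_poi_genotypes",
]


@dataclass(frozen=True)
class Hypothesis:
    """A proposition about the trace: n contributors, eta of them known POIs."""

    n: int
    pois: tuple[ReferenceProfile, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"number of contributors must be >= 1, got {self.n}")
        if len(self.pois) > self.n:
            raise ValueError(
                f"{len(self.pois)} POIs exceed the {self.n} hypothesized contributors"
            )
        if not self.label:
            ids = "+".join(p.sample_id for p in self.pois)
            us = "U" * (self.n - len(self.pois))
            object.__setattr__(self, "label", "+".join(x for x in (ids, us) if x))

    @property
    def eta(self) -> int:
        return len(self.pois)


@dataclass(frozen=True)
class LocusLikelihood:
    """A per-locus likelihood with its dispatch cell and formula tag."""

    locus_id: str
    value: float
    case_label: str
    formula: str

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.value <= 1.0 + 1e-12):
            raise ValueError(
                f"{self.locus_id}: likelihood {self.value} outside [0,1] "
                f"(case {self.case_label})"
            )


def h_index(ev: LocusEvidence, h_min: float | None = None) -> float:
    """Heterozygote-balance index: minor read divided by major read.

    When the minor read is zero the raw ratio would zero out every dropout
    likelihood irrecoverably, so the index is floored at ``h_min``
    (default ``1/(Q_a + 1)``, i.e. just below the resolution of the record).
    """
    if ev.q_a <= 0:
        raise ValueError(f"{ev.locus_id}: h index undefined without major reads")
    if ev.q_b == 0:
        return h_min if h_min is not None else 1.0 / (ev.q_a + 1)
    return ev.q_b / ev.q_a


# --- individual formulas ---------------------------------------------------
# Compatible cells, biallelic evidence:

def compat_hom_major(f_a: float, n: int, eta: int) -> float:
    """P(E{a;b} | POIs all AA) = 1 - f_a**(2(n-eta))."""
    return 1.0 - f_a ** (2 * (n - eta))


def compat_hom_minor(f_b: float, n: int, eta: int) -> float:
    """P(E{a;b} | POIs all BB) = 1 - f_b**(2(n-eta))."""
    return 1.0 - f_b ** (2 * (n - eta))


def deconv_biallelic(f_a: float, f_b: float, n: int) -> float:
    """P(E{a;b} | n unknowns) = 1 - f_a**(2n) - f_b**(2n)."""
    return 1.0 - f_a ** (2 * n) - f_b ** (2 * n)


# Dropout cells, monoallelic evidence E{a} read as E{a;b_d}:

def dropout_latent_major(f_a: float, n: int, eta: int, h: float) -> float:
    """P(E{a;b_d} | POIs all AA) = (1-h) * f_a**(2(n-eta)): compatible, latent dropout."""
    return (1.0 - h) * f_a ** (2 * (n - eta))


def dropout_hom_minor(f_b: float, n: int, eta: int, h: float) -> float:
    """P(E{a;b_d} | POI BB) = h**2 * f_b**(2(n-eta)): both POI alleles dropped."""
    return h * h * f_b ** (2 * (n - eta))


def dropout_het(h: float) -> float:
    """P(E{a;b_d} | POI AB) = h: the POI's minor allele dropped."""
    return h


def deconv_monoallelic(f_a: float, f_b: float, n: int, h: float) -> float:
    """P(E{a;b_d} | n unknowns): total-probability blend of the three dropout cells.

    All-major-homozygote assortments produce genuinely monoallelic evidence
    (weight 1-h), mixed assortments require the minor allele to drop (weight
    h), all-minor-homozygote assortments require a double drop (weight h**2).
    """
    pa = f_a ** (2 * n)
    pb = f_b ** (2 * n)
    return (1.0 - h) * pa + h * (1.0 - pa - pb) + h * h * pb


# Vestigial mirror cells (the major allele dropped).  Under the canonical
# relabeling Q_a >= Q_b the major read cannot vanish while the minor
# survives, so these are never dispatched; they are kept so the inferential
# table is total.

def dropout_latent_minor(f_b: float, n: int, eta: int, h: float) -> float:
    """P(E{a_d;b} | POIs all BB) = (1-h) * f_b**(2(n-eta)); unreachable."""
    return (1.0 - h) * f_b ** (2 * (n - eta))


def dropout_hom_major(f_a: float, n: int, eta: int, h: float) -> float:
    """P(E{a_d;b} | POI AA) = h**2 * f_a**(2(n-eta)); unreachable."""
    return h * h * f_a ** (2 * (n - eta))


# --- dispatch --------------------------------------------------------------

def semicont_likelihood(
    ev_class: EvidenceClass,
    pois: Sequence[Genotype],
    n: int,
    freqs: LocusFrequencies,
    h: float,
    locus_id: str | None = None,
) -> LocusLikelihood:
    """Dispatch one locus to its semi-continuous likelihood cell.

    ``pois`` are the POI genotypes already expressed in the locus's a/b
    codes; ``eta = len(pois)``.  With several POIs the most constraining one
    selects the cell and the full eta is subtracted in the exponent.
    """
    eta = len(pois)
    if eta > n:
        raise ValueError(f"eta={eta} exceeds n={n}")
    locus_id = locus_id if locus_id is not None else freqs.locus_id
    f_a, f_b = freqs.f_a, freqs.f_b
    any_ab = Genotype.AB in pois
    any_aa = Genotype.AA in pois
    any_bb = Genotype.BB in pois

    if ev_class is EvidenceClass.BIALLELIC:
        if eta == 0:
            value, case, tag = deconv_biallelic(f_a, f_b, n), "E{a;b}|deconv", "deconv-bi"
        elif any_ab or (any_aa and any_bb):
            value, case, tag = 1.0, "E{a;b}|K{a;b}", "match"
        elif any_aa:
            value, case, tag = compat_hom_major(f_a, n, eta), "E{a;b}|K{a}", "compat-AA"
        else:
            value, case, tag = compat_hom_minor(f_b, n, eta), "E{a;b}|K{b}", "compat-BB"
    else:
        if eta == 0:
            value = deconv_monoallelic(f_a, f_b, n, h)
            case, tag = "E{a;bd}|deconv", "deconv-mono"
        elif any_bb:
            value = dropout_hom_minor(f_b, n, eta, h)
            case, tag = "E{a;bd}|K{b}", "drop-BB"
        elif any_ab:
            value, case, tag = dropout_het(h), "E{a;bd}|K{a;b}", "drop-AB"
        else:
            value = dropout_latent_major(f_a, n, eta, h)
            case, tag = "E{a;bd}|K{a}", "latent-AA"
    return LocusLikelihood(locus_id, min(max(value, 0.0), 1.0), case, tag)


def resolve_poi_genotypes(
    hypothesis: Hypothesis,
    freqs: LocusFrequencies,
    notes: list[str] | None = None,
) -> list[Genotype]:
    """POI genotypes at one locus in its a/b codes.

    A POI whose profile does not cover the locus (or names an allele foreign
    to it) is omitted *at that locus only* — eta drops locally — and the
    omission is reported in ``notes`` rather than silently discarded.
    """
    genotypes: list[Genotype] = []
    for poi in hypothesis.pois:
        try:
            genotypes.append(poi.resolve(freqs))
        except (KeyError, ValueError) as exc:
            if notes is not None:
                notes.append(
                    f"locus {freqs.locus_id}: POI {poi.sample_id} unresolvable "
                    f"({exc if isinstance(exc, ValueError) else 'locus not typed'}); "
                    "treated as unknown at this locus"
                )
    return genotypes


Dataset = Sequence[tuple[LocusEvidence, LocusFrequencies]]


def semicont_lr(
    numerator: Hypothesis,
    denominator: Hypothesis,
    dataset: Dataset,
    drop_infinite: bool = False,
) -> LRReport:
    """Protocol-wide semi-continuous LR (numerator over denominator).

    The per-locus LR is the ratio of the two dispatch values; the protocol
    LR is their product over usable loci, accumulated as a sum of log10
    values.  A locus whose denominator likelihood is zero is flagged and its
    LR reported as +infinity; it is kept in the product unless
    ``drop_infinite`` is set.
    """
    if numerator.eta - denominator.eta < 1:
        warnings.warn(
            "the numerator usually carries at least one more POI than the "
            f"denominator (eta_num={numerator.eta}, eta_den={denominator.eta})",
            stacklevel=2,
        )
    notes: list[str] = []
    rows = []
    total = 0.0
    for ev, freqs in dataset:
        if not ev.usable:
            notes.append(f"locus {ev.locus_id}: no reads, excluded")
            continue
        h = h_index(ev)
        ev_class = ev.evidence_class
        g_num = resolve_poi_genotypes(numerator, freqs, notes)
        g_den = resolve_poi_genotypes(denominator, freqs, notes)
        l_num = semicont_likelihood(ev_class, g_num, numerator.n, freqs, h)
        l_den = semicont_likelihood(ev_class, g_den, denominator.n, freqs, h)
        infinite = l_den.value == 0.0 and l_num.value > 0.0
        if l_num.value == 0.0 and l_den.value == 0.0:
            log10_lr = 0.0
            notes.append(f"locus {ev.locus_id}: both likelihoods zero, uninformative")
        elif infinite:
            log10_lr = math.inf
            notes.append(f"locus {ev.locus_id}: denominator likelihood is zero")
        elif l_num.value == 0.0:
            log10_lr = -math.inf
        else:
            log10_lr = math.log10(l_num.value) - math.log10(l_den.value)
        if not (infinite and drop_infinite):
            total += log10_lr
        rows.append(
            {
                "locus_id": ev.locus_id,
                "evidence_class": ev_class.value,
                "case_num": l_num.case_label,
                "case_den": l_den.case_label,
                "L_num": l_num.value,
                "L_den": l_den.value,
                "log10_lr": log10_lr,
                "ceiling": float("nan"),
                "ceiling_flag": False,
                "infinite": infinite,
            }
        )
    per_locus = pd.DataFrame(rows, columns=PER_LOCUS_COLUMNS)
    return LRReport(
        engine="semicont",
        label_num=numerator.label,
        label_den=denominator.label,
        per_locus=per_locus,
        log10_lr=total,
        notes=notes,
        metadata={
            "n_num": numerator.n,
            "eta_num": numerator.eta,
            "n_den": denominator.n,
            "eta_den": denominator.eta,
            "drop_infinite": drop_infinite,
        },
    )


def dropin_scan(
    numerator: Hypothesis,
    denominator: Hypothesis,
    dataset: Dataset,
    k_extra: int,
    max_n: int = 8,
) -> list[LRReport]:
    """Re-run the LR under n, n+1, ..., n+k_extra contributors.

    Dropin alleles are modeled as extra contributors, so scanning upward in n
    brackets the effect of unattributed alleles on the LR.
    """
    if k_extra < 0:
        raise ValueError("k_extra must be >= 0")
    if max(numerator.n, denominator.n) + k_extra > max_n:
        raise ValueError(
            f"n + k_extra exceeds the configured maximum of {max_n} contributors"
        )
    reports = []
    for k in range(k_extra + 1):
        num_k = replace(numerator, n=numerator.n + k, label="")
        den_k = replace(denominator, n=denominator.n + k, label="")
        reports.append(semicont_lr(num_k, den_k, dataset))
    return reports
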