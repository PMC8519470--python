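"""Quantitative (fully continuous) likelihoods for biallelic mixtures.

The continuous engine augments the combinatorial model with the read counts.
Three independent indices are attached to every permutation state of a locus:

1. the **Mendelian index** — the product of the population genotype
   frequencies of the unknown contributors in the state;
2. the **state h index** — how plausible the state's heterozygote balance is
   given the observed major/minor reads;
3. the **(1 - chi^2) weight** — how well the mixture ratio implied by the
   state (MR_obs) agrees with the protocol-wide expected ratio (MR_ex)
   anchored by the person of interest's unique genotypes.

The three indices multiply per state and the products sum over the
(conditioned) permutation matrix to a per-locus likelihood.  With the h
index and the weight forced to 1 the sum collapses to the semi-continuous
value of the same dispatch cell.

Quantity apportionment follows Mendelian dose rules per combination class
(total ``T = Q_a + Q_b``):

==============  ==========================================================
class           group quantities
==============  ==========================================================
rAA+sBB         AA group ``Q_a``; BB group ``Q_b``
rAA+sAB         AA group ``Q_a - Q_b``; AB group ``2*Q_b``
rAA+sAB+tBB     AB group ``(Q_a**2 + Q_b**2)/T``; the remainder
                ``2*Q_a*Q_b/T`` split equally between AA and BB
rAB+sBB         BB group ``Q_b*2s/(2s + r)``; AB group the rest
nAB             single group ``T``
==============  ==========================================================

(r and s are the multiplicities named in the class; quantities always
conserve ``T``.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    CombinationClass,
    EvidenceClass,
    Genotype,
    LocusEvidence,
    LocusFrequencies,
    ReferenceProfile,
    classify_combination,
    condition_on_pois,
    enumerate_permutations,
    genotype_counts,
)
from .report import PER_LOCUS_COLUMNS, LRReport
from .semicontinuous import (
    Dataset,
    Hypothesis,
    LocusLikelihood,
    h_index,
    resolve_poi_genotypes,
    semicont_likelihood,
)

__all__ = [
    "MixRatio",
    "UniqueGenotypeLabel",
    "apportion_quantities",
    "flag_unrealistic",
    "unique_genotypes",
    "unique_quantity",
    "mr_ex",
    "mr_obs",
    "contributor_fractions",
    "state_h",
    "chi2_weight",
    "continuous_likelihood",
    "continuous_lr",
    "matrix_table",
    "protocol_state_table",
]

#: Floor on an expected fraction in the chi-square denominator.
_EXP_FLOOR = 1e-6


@dataclass(frozen=True)
class MixRatio:
    """DNA fractions of the contributors, POI component first, summing to 1.

    The unknown contributors are pooled: they all receive the same fraction
    (the engine cannot tell anonymous contributors apart).
    """

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("a mixture ratio needs at least one component")
        if any(f < -1e-9 or f > 1.0 + 1e-9 for f in self.fractions):
            raise ValueError(f"fractions outside [0,1]: {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")

    @classmethod
    def from_poi_fraction(cls, poi_fraction: float, n: int) -> "MixRatio":
        """POI-first ratio with the remainder split equally over n-1 unknowns."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if n == 1:
            return cls((1.0,))
        rest = (1.0 - poi_fraction) / (n - 1)
        return cls((poi_fraction,) + (rest,) * (n - 1))

    @property
    def n(self) -> int:
        return len(self.fractions)

    @property
    def poi_fraction(self) -> float:
        return self.fractions[0]

    @property
    def two_component(self) -> tuple[float, float]:
        """Collapse to (POI, pooled unknowns)."""
        return (self.fractions[0], 1.0 - self.fractions[0])


class UniqueGenotypeLabel(Enum):
    """Uniqueness of a genotype group within a permutation state.

    NOG: non-redundant, non-overlapping (parsimonious AA+(n-1)BB shapes);
    SOG: non-redundant, simply overlapping (AA+(n-1)AB shapes).  A unique
    genotype shares its DNA amount with no other contributor, so its
    quantity is directly attributable.
    """

    NOG = "NOG"
    SOG = "SOG"
    NONE = "none"


def apportion_quantities(
    genotypes: tuple[Genotype, ...], q_a: float, q_b: float
) -> dict[Genotype, float]:
    """Distribute the locus reads over the genotype groups of one state.

    Identical genotypes cannot be told apart, so each genotype *group*
    receives one amount (its members share it equally downstream).  The
    rAA+sAB+tBB remainder is split equally between the AA and BB groups,
    which conserves the total and gives each group its per-allele share
    ``Q_a*Q_b/T``.
    """
    if not (q_a >= q_b > 0):
        raise ValueError(f"apportionment requires Q_a >= Q_b > 0, got {q_a}, {q_b}")
    total = q_a + q_b
    cls = classify_combination(genotypes)
    n_aa, n_ab, n_bb = genotype_counts(genotypes)
    if cls is CombinationClass.R_AA_S_BB:
        return {Genotype.AA: float(q_a), Genotype.BB: float(q_b)}
    if cls is CombinationClass.R_AA_S_AB:
        return {Genotype.AA: float(q_a - q_b), Genotype.AB: 2.0 * q_b}
    if cls is CombinationClass.R_AA_S_AB_T_BB:
        q_ab = (q_a * q_a + q_b * q_b) / total
        half_rest = q_a * q_b / total
        return {Genotype.AA: half_rest, Genotype.AB: q_ab, Genotype.BB: half_rest}
    if cls is CombinationClass.R_AB_S_BB:
        q_bb = q_b * 2.0 * n_bb / (2.0 * n_bb + n_ab)
        return {Genotype.AB: total - q_bb, Genotype.BB: q_bb}
    return {Genotype.AB: float(total)}


def flag_unrealistic(genotypes: tuple[Genotype, ...]) -> bool:
    """True if the state implies more minor- than major-allele molecules.

    Under balanced heterozygotes the a dose is ``2*n_AA + n_AB`` and the b
    dose ``2*n_BB + n_AB``; a state with more BB than AA contributors
    contradicts ``Q_a >= Q_b`` and is excluded from unique-genotype
    (MR_ex) harvesting, though it stays in the likelihood sum.
    """
    n_aa, _, n_bb = genotype_counts(genotypes)
    return n_bb > n_aa


def unique_genotypes(
    genotypes: tuple[Genotype, ...]
) -> dict[Genotype, UniqueGenotypeLabel]:
    """Label each genotype group of a state as NOG, SOG or neither.

    Only singleton groups in the two parsimonious shapes qualify:
    rAA+sBB singletons are NOGs (their alleles overlap nothing) and
    rAA+sAB singletons are SOGs (the AA group overlaps the heterozygote
    at the shared 'a' allele).
    """
    cls = classify_combination(genotypes)
    n_aa, n_ab, n_bb = genotype_counts(genotypes)
    labels = {g: UniqueGenotypeLabel.NONE for g in set(genotypes)}
    if cls is CombinationClass.R_AA_S_BB:
        if n_aa == 1:
            labels[Genotype.AA] = UniqueGenotypeLabel.NOG
        if n_bb == 1:
            labels[Genotype.BB] = UniqueGenotypeLabel.NOG
    elif cls is CombinationClass.R_AA_S_AB:
        if n_aa == 1:
            labels[Genotype.AA] = UniqueGenotypeLabel.SOG
        if n_ab == 1:
            labels[Genotype.AB] = UniqueGenotypeLabel.SOG
    return labels


def unique_quantity(
    genotype: Genotype,
    label: UniqueGenotypeLabel,
    q_a: float,
    q_b: float,
) -> float:
    """Directly attributable DNA amount of a unique genotype.

    NOG AA -> Q_a; NOG BB -> Q_b; SOG AA -> Q_a - Q_b; SOG AB -> 2*Q_b.
    """
    if label is UniqueGenotypeLabel.NOG:
        return float(q_a) if genotype is Genotype.AA else float(q_b)
    if label is UniqueGenotypeLabel.SOG:
        return float(q_a - q_b) if genotype is Genotype.AA else 2.0 * float(q_b)
    raise ValueError("only NOG/SOG groups have a directly attributable quantity")


def mr_ex(
    poi: ReferenceProfile,
    dataset: Dataset,
    n: int,
) -> MixRatio:
    """Protocol-wide expected mixture ratio anchored by the POI.

    Biallelic loci are partitioned by the POI's a/b genotype; the unique
    (SOG/NOG) quantities attributable to the POI and to the unknowns are
    summed over the whole protocol:

    POI AA loci contribute ``Q_a - Q_b`` to the POI and ``2*Q_b`` to the
    unknowns; POI AB loci ``2*Q_b`` and ``Q_a - Q_b``; POI BB loci ``Q_b``
    and ``Q_a``.  Monoallelic and untyped loci are excluded.  The unknown
    share is split equally over the n-1 unknowns.

    For a true contributor the estimate tracks their real DNA fraction; for
    a non-contributor it drifts to the balanced ratio 1/n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    q_poi = 0.0
    q_unknown = 0.0
    used = 0
    for ev, freqs in dataset:
        if not ev.usable or ev.evidence_class is not EvidenceClass.BIALLELIC:
            continue
        try:
            g = poi.resolve(freqs)
        except (KeyError, ValueError):
            continue
        if g is Genotype.AA:
            q_poi += ev.q_a - ev.q_b
            q_unknown += 2.0 * ev.q_b
        elif g is Genotype.AB:
            q_poi += 2.0 * ev.q_b
            q_unknown += ev.q_a - ev.q_b
        else:
            q_poi += ev.q_b
            q_unknown += ev.q_a
        used += 1
    if used == 0:
        raise ValueError(
            f"MR_ex for {poi.sample_id}: no usable biallelic locus with a "
            "resolvable POI genotype"
        )
    total = q_poi + q_unknown
    if total <= 0:
        raise ValueError(f"MR_ex for {poi.sample_id}: zero total unique quantity")
    return MixRatio.from_poi_fraction(q_poi / total, n)


def contributor_fractions(
    genotypes: tuple[Genotype, ...],
    quantities: Mapping[Genotype, float],
    total: float,
) -> tuple[float, ...]:
    """Per-contributor DNA fractions: group quantity shared equally in-group."""
    n_aa, n_ab, n_bb = genotype_counts(genotypes)
    sizes = {Genotype.AA: n_aa, Genotype.AB: n_ab, Genotype.BB: n_bb}
    return tuple(quantities[g] / sizes[g] / total for g in genotypes)


def mr_obs(
    genotypes: tuple[Genotype, ...],
    q_a: float,
    q_b: float,
    poi_index: int,
    mr_expected: MixRatio,
    quantities: Mapping[Genotype, float] | None = None,
) -> MixRatio:
    """Observed mixture ratio of one permutation state, POI component first.

    The POI's amount is its genotype group's quantity divided equally among
    the group members; the unknowns pool the remainder equally.  A fully
    redundant state (every contributor the identical genotype) carries no
    quantitative information about who-is-who, so its MR_obs is taken to be
    MR_ex itself (the chi-square weight is then exactly 1).
    """
    n = len(genotypes)
    if len(set(genotypes)) == 1:
        return mr_expected
    if quantities is None:
        quantities = apportion_quantities(genotypes, q_a, q_b)
    total = q_a + q_b
    g = genotypes[poi_index]
    counts = genotype_counts(genotypes)
    size = counts[int(g)]
    poi_fraction = quantities[g] / size / total
    poi_fraction = min(max(poi_fraction, 0.0), 1.0)
    return MixRatio.from_poi_fraction(poi_fraction, n)


def state_h(genotypes: tuple[Genotype, ...], q_a: float, q_b: float) -> float:
    """Per-state heterozygote-plausibility index, clamped to [0,1].

    Measures how balanced the heterozygote group's implied allele shares
    are, given the state's apportionment:

    - ``nAB`` and ``rAA+sBB``: the raw locus balance ``Q_b/Q_a``;
    - ``rAA+sAB``: 1 (the rule gives the heterozygote equal a and b shares);
    - ``rAB+sBB``: the BB group's amount over ``Q_a``;
    - ``rAA+sAB+tBB``: the AB group's b share over its a share
      (``Q_b**2 / Q_a**2`` under the dose apportionment).
    """
    cls = classify_combination(genotypes)
    if cls is CombinationClass.R_AA_S_AB:
        return 1.0
    if cls in (CombinationClass.N_AB, CombinationClass.R_AA_S_BB):
        value = q_b / q_a
    elif cls is CombinationClass.R_AB_S_BB:
        _, n_ab, n_bb = genotype_counts(genotypes)
        value = (q_b * 2.0 * n_bb / (2.0 * n_bb + n_ab)) / q_a
    else:  # R_AA_S_AB_T_BB
        value = (q_b * q_b) / (q_a * q_a)
    return min(max(value, 0.0), 1.0)


def chi2_weight(
    observed: MixRatio | Sequence[float],
    expected: MixRatio | Sequence[float],
) -> float:
    """(1 - chi^2) plausibility weight of an observed mixture ratio.

    Pearson statistic on the two-component (POI vs pooled-unknowns) fraction
    vectors, subtracted from 1 and clamped to [0,1].  Equals exactly 1 when
    the observed ratio matches the expected one; expected components are
    floored at 1e-6 in the denominator.
    """
    obs = observed.two_component if isinstance(observed, MixRatio) else tuple(observed)
    exp = expected.two_component if isinstance(expected, MixRatio) else tuple(expected)
    if len(obs) != len(exp):
        raise ValueError("observed and expected ratios must have the same length")
    stat = sum((o - e) ** 2 / max(e, _EXP_FLOOR) for o, e in zip(obs, exp))
    return min(max(1.0 - stat, 0.0), 1.0)


def continuous_likelihood(
    ev: LocusEvidence,
    freqs: LocusFrequencies,
    pois: Sequence[Genotype],
    n: int,
    mr_expected: MixRatio | None,
    state_weights: Mapping[tuple[Genotype, ...], float] | None = None,
    fixed_h: float | None = None,
    fixed_weight: float | None = None,
) -> LocusLikelihood:
    """Three-index continuous likelihood of one biallelic locus.

    Sums, over the permutation states conditioned on the POI genotypes, the
    product of the Mendelian index (genotype frequencies of the unknown
    columns), the state h index and the (1 - chi^2) weight.  The weight is
    anchored on ``mr_expected``; with no POI there is no anchor (the
    expected ratio equalizes and constrains nothing), so every state takes
    weight 1.

    ``state_weights`` (keyed by the genotype tuple), ``fixed_h`` and
    ``fixed_weight`` override the computed indices; they exist for
    reproducing externally supplied per-state weights and for the
    degeneracy check against the semi-continuous model.
    """
    eta = len(pois)
    if eta > n:
        raise ValueError(f"eta={eta} exceeds n={n}")
    if ev.evidence_class is EvidenceClass.MONOALLELIC:
        raise ValueError(
            f"{ev.locus_id}: continuous_likelihood requires biallelic evidence; "
            "monoallelic loci use the semi-continuous dispatch"
        )
    matrix = condition_on_pois(enumerate_permutations(n), list(pois))
    case = semicont_likelihood(EvidenceClass.BIALLELIC, pois, n, freqs, 1.0).case_label
    value = 0.0
    for state in matrix.states:
        g = state.genotypes
        mend = 1.0
        for col in range(eta, n):
            mend *= freqs.genotype_frequency(g[col])
        h_s = fixed_h if fixed_h is not None else state_h(g, ev.q_a, ev.q_b)
        if fixed_weight is not None:
            w = fixed_weight
        elif state_weights is not None and g in state_weights:
            w = state_weights[g]
        elif eta == 0 or mr_expected is None:
            w = 1.0
        else:
            obs = mr_obs(g, ev.q_a, ev.q_b, 0, mr_expected)
            w = chi2_weight(obs, mr_expected)
        value += mend * h_s * w
    return LocusLikelihood(ev.locus_id, min(value, 1.0), case, "three-index")


def continuous_lr(
    numerator: Hypothesis,
    denominator: Hypothesis,
    dataset: Dataset,
    mrex_override: float | None = None,
    state_weights: Mapping[tuple[Genotype, ...], float] | None = None,
    drop_infinite: bool = False,
) -> LRReport:
    """Protocol-wide continuous (three-index) LR.

    MR_ex is computed once per hypothesis over the whole protocol (or taken
    from ``mrex_override``, the POI fraction, for the numerator).  Biallelic
    loci use the three-index likelihood; monoallelic loci fall back to the
    semi-continuous dropout dispatch with the locus h.  The per-locus report
    carries the single-source ceiling ``1/P(GT_POI)`` and flags any locus LR
    exceeding it.

    The quantitative weight is a two-component POI-vs-unknowns construct, so
    each hypothesis may carry at most one POI under this engine.
    """
    for hyp, side in ((numerator, "numerator"), (denominator, "denominator")):
        if hyp.eta > 1:
            raise ValueError(
                f"the continuous engine supports at most one POI per hypothesis "
                f"({side} has {hyp.eta}); use the semi-continuous engine for more"
            )
    notes: list[str] = []

    def hypothesis_mrex(hyp: Hypothesis, override: float | None) -> MixRatio | None:
        if hyp.eta == 0:
            return None
        if override is not None:
            return MixRatio.from_poi_fraction(override, hyp.n)
        return mr_ex(hyp.pois[0], dataset, hyp.n)

    mrex_num = hypothesis_mrex(numerator, mrex_override)
    mrex_den = hypothesis_mrex(denominator, None)

    def locus_likelihood(
        hyp: Hypothesis,
        mrex: MixRatio | None,
        ev: LocusEvidence,
        freqs: LocusFrequencies,
        h: float,
        weights: Mapping[tuple[Genotype, ...], float] | None,
    ) -> LocusLikelihood:
        g = resolve_poi_genotypes(hyp, freqs, notes)
        if ev.evidence_class is EvidenceClass.MONOALLELIC:
            return semicont_likelihood(ev.evidence_class, g, hyp.n, freqs, h)
        return continuous_likelihood(ev, freqs, g, hyp.n, mrex, state_weights=weights)

    rows = []
    total = 0.0
    for ev, freqs in dataset:
        if not ev.usable:
            notes.append(f"locus {ev.locus_id}: no reads, excluded")
            continue
        h = h_index(ev)
        l_num = locus_likelihood(numerator, mrex_num, ev, freqs, h, state_weights)
        l_den = locus_likelihood(denominator, mrex_den, ev, freqs, h, None)
        if l_num.value == 0.0 and l_den.value == 0.0:
            log10_lr, infinite = 0.0, False
            notes.append(f"locus {ev.locus_id}: both likelihoods zero, uninformative")
        elif l_den.value == 0.0:
            log10_lr, infinite = math.inf, True
            notes.append(f"locus {ev.locus_id}: denominator likelihood is zero")
        elif l_num.value == 0.0:
            log10_lr, infinite = -math.inf, False
        else:
            log10_lr = math.log10(l_num.value) - math.log10(l_den.value)
            infinite = False
        ceiling = float("nan")
        ceiling_flag = False
        if numerator.eta == 1:
            try:
                g_poi = numerator.pois[0].resolve(freqs)
            except (KeyError, ValueError):
                g_poi = None
            if g_poi is not None:
                p_gt = freqs.genotype_frequency(g_poi)
                ceiling = 1.0 / p_gt
                ceiling_flag = (
                    math.isfinite(log10_lr)
                    and 10.0 ** log10_lr > ceiling * (1 + 1e-9)
                ) or (math.isinf(log10_lr) and log10_lr > 0)
        if not (infinite and drop_infinite):
            total += log10_lr
        rows.append(
            {
                "locus_id": ev.locus_id,
                "evidence_class": ev.evidence_class.value,
                "case_num": l_num.case_label,
                "case_den": l_den.case_label,
                "L_num": l_num.value,
                "L_den": l_den.value,
                "log10_lr": log10_lr,
                "ceiling": ceiling,
                "ceiling_flag": ceiling_flag,
                "infinite": infinite,
            }
        )
    per_locus = pd.DataFrame(rows, columns=PER_LOCUS_COLUMNS)
    return LRReport(
        engine="continuous",
        label_num=numerator.label,
        label_den=denominator.label,
        per_locus=per_locus,
        log10_lr=total,
        mr_ex=mrex_num.fractions if mrex_num is not None else None,
        notes=notes,
        metadata={
            "n_num": numerator.n,
            "eta_num": numerator.eta,
            "n_den": denominator.n,
            "eta_den": denominator.eta,
            "mrex_override": mrex_override,
            "drop_infinite": drop_infinite,
        },
    )


def matrix_table(
    n: int,
    q_a: float | None = None,
    q_b: float | None = None,
) -> pd.DataFrame:
    """The n-contributor permutation matrix as a table, one row per state.

    With read counts supplied, each row also carries the apportioned group
    quantities, per-contributor fractions, the state h index, the realism
    flag and the NOG/SOG labels — the tabular analogue of a worked
    deconvolution worksheet.
    """
    rows = []
    for state in enumerate_permutations(n).states:
        g = state.genotypes
        row: dict[str, object] = {
            "state": "+".join(x.name for x in g),
            "class": classify_combination(g).value,
            "unrealistic": flag_unrealistic(g),
        }
        labels = unique_genotypes(g)
        row["unique_labels"] = ";".join(
            f"{geno.name}={lab.value}"
            for geno, lab in sorted(labels.items())
            if lab is not UniqueGenotypeLabel.NONE
        )
        if q_a is not None and q_b is not None:
            quantities = apportion_quantities(g, q_a, q_b)
            fracs = contributor_fractions(g, quantities, q_a + q_b)
            for geno in (Genotype.AA, Genotype.AB, Genotype.BB):
                row[f"Q_{geno.name}"] = quantities.get(geno, 0.0)
            row["mr_state"] = ":".join(f"{f:.4f}" for f in fracs)
            row["h_state"] = state_h(g, q_a, q_b)
        rows.append(row)
    return pd.DataFrame(rows)


def protocol_state_table(dataset: Dataset, n: int) -> pd.DataFrame:
    """One row per (biallelic locus, permutation state) across a protocol.

    Every row carries that state's observed mixture ratio, so the row count
    is the number of MR_obs values the protocol generates (e.g. 7 states x
    133 loci = 931 for a two-person analysis).
    """
    frames = []
    for ev, freqs in dataset:
        if not ev.usable or ev.evidence_class is not EvidenceClass.BIALLELIC:
            continue
        tab = matrix_table(n, ev.q_a, ev.q_b)
        tab.insert(0, "locus_id", ev.locus_id)
        frames.append(tab)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
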