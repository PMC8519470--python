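"""Quantity apportionment, unique genotypes, MR estimation and the
three-index continuous likelihood."""

from __future__ import annotations


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpmixlr import (
    EvidenceClass,
    Genotype,
    Hypothesis,
    LocusEvidence,
    LocusFrequencies,
    MixRatio,
    ReferenceProfile,
    SimulationConfig,
    UniqueGenotypeLabel,
    apportion_quantities,
    chi2_weight,
    continuous_likelihood,
    continuous_lr,
    enumerate_permutations,
    flag_unrealistic,
    matrix_table,
    mr_ex,
    mr_obs,
    sample_profiles,
    semicont_likelihood,
    simulate_mixture,
    state_h,
    unique_genotypes,
)
from snpmixlr.quantitative import unique_quantity

G = Genotype

#: The worked-example weights as externally supplied per-state inputs: the
#: publication's chi-square convention for the AB+BB and AB+AA cells is not
#: recoverable from the printed ratios, so these are treated as given.
WORKED_WEIGHTS = {
    (G.AB, G.AB): 1.0,
    (G.AB, G.BB): 0.169,
    (G.AB, G.AA): 0.924,
}


class TestApportionment:
    def test_het_plus_hom_minor(self):
        """(AB,BB) at 739/704: the BB group takes 2*704/3 of the minor reads."""
        q = apportion_quantities((G.AB, G.BB), 739, 704)
        assert q[G.BB] == pytest.approx(2 * 704 / 3)
        assert q[G.AB] == pytest.approx(739 + 704 - 2 * 704 / 3)

    def test_het_plus_hom_major(self):
        q = apportion_quantities((G.AB, G.AA), 739, 704)
        assert q[G.AB] == pytest.approx(1408.0)
        assert q[G.AA] == pytest.approx(35.0)

    def test_all_het_single_group(self):
        q = apportion_quantities((G.AB, G.AB), 739, 704)
        assert q == {G.AB: pytest.approx(1443.0)}

    def test_full_assortment_split(self):
        """rAA+sAB+tBB: AB takes (Qa^2+Qb^2)/T, AA and BB split the rest."""
        q = apportion_quantities((G.AA, G.AB, G.BB), 600, 400)
        assert q[G.AB] == pytest.approx((600**2 + 400**2) / 1000)
        assert q[G.AA] == q[G.BB] == pytest.approx(600 * 400 / 1000)

    def test_requires_minor_reads(self):
        with pytest.raises(ValueError):
            apportion_quantities((G.AB, G.BB), 100, 0)

    @settings(max_examples=100, derandomize=True)
    @given(
        n=st.integers(1, 5),
        index=st.integers(0, 3**5 - 3),
        qa=st.integers(1, 100_000),
        qb=st.integers(1, 100_000),
    )
    def test_conservation(self, n, index, qa, qb):
        """Group quantities always sum to Q_a + Q_b, in every class."""
        states = enumerate_permutations(n).states
        genotypes = states[index % len(states)].genotypes
        qa, qb = max(qa, qb), min(qa, qb)
        q = apportion_quantities(genotypes, qa, qb)
        assert sum(q.values()) == pytest.approx(qa + qb, rel=1e-12)


class TestRealismFlag:
    @pytest.mark.parametrize(
        "genotypes,expected",
        [
            ((G.AB, G.BB), True),   # more b than a molecules implied
            ((G.BB, G.AB), True),
            ((G.AA, G.AB), False),
            ((G.AA, G.BB), False),
            ((G.AB, G.AB), False),
            ((G.AA, G.BB, G.BB), True),
        ],
    )
    def test_examples(self, genotypes, expected):
        assert flag_unrealistic(genotypes) is expected


class TestUniqueGenotypes:
    def test_nog_in_hom_only_state(self):
        labels = unique_genotypes((G.AA, G.BB, G.BB))
        assert labels[G.AA] is UniqueGenotypeLabel.NOG
        assert labels[G.BB] is UniqueGenotypeLabel.NONE
        assert unique_quantity(G.AA, labels[G.AA], 900, 100) == 900.0

    def test_sog_in_hom_het_state(self):
        labels = unique_genotypes((G.AA, G.AB, G.AB))
        assert labels[G.AA] is UniqueGenotypeLabel.SOG
        assert unique_quantity(G.AA, labels[G.AA], 900, 100) == 800.0
        labels2 = unique_genotypes((G.AA, G.AA, G.AB))
        assert labels2[G.AB] is UniqueGenotypeLabel.SOG
        assert unique_quantity(G.AB, labels2[G.AB], 900, 100) == 200.0

    def test_redundant_groups_have_no_unique(self):
        labels = unique_genotypes((G.AB, G.AB))
        assert labels[G.AB] is UniqueGenotypeLabel.NONE

    def test_full_assortment_has_no_unique(self):
        labels = unique_genotypes((G.AA, G.AB, G.BB))
        assert all(l is UniqueGenotypeLabel.NONE for l in labels.values())

    def test_both_noG_in_two_person_hom_state(self):
        labels = unique_genotypes((G.AA, G.BB))
        assert labels[G.AA] is labels[G.BB] is UniqueGenotypeLabel.NOG


class TestStateH:
    def test_worked_example_cells(self):
        assert state_h((G.AB, G.AB), 739, 704) == pytest.approx(0.952, abs=1e-3)
        assert state_h((G.AB, G.AA), 739, 704) == 1.0
        assert state_h((G.AB, G.BB), 739, 704) == pytest.approx(0.635, abs=5e-4)

    def test_full_assortment_cell(self):
        assert state_h((G.AA, G.AB, G.BB), 800, 200) == pytest.approx((200 / 800) ** 2)

    def test_hom_only_cell_uses_locus_balance(self):
        assert state_h((G.AA, G.BB), 800, 200) == pytest.approx(0.25)

    def test_clamped_to_unit_interval(self):
        for state in enumerate_permutations(3).states:
            v = state_h(state.genotypes, 505, 495)
            assert 0.0 <= v <= 1.0


class TestMrObs:
    def test_worked_example_ratios(self):
        mrex = MixRatio.from_poi_fraction(0.94, 2)
        ab_aa = mr_obs((G.AB, G.AA), 739, 704, 0, mrex)
        assert ab_aa.fractions[0] == pytest.approx(0.976, abs=5e-4)
        ab_bb = mr_obs((G.AB, G.BB), 739, 704, 0, mrex)
        assert ab_bb.fractions[0] == pytest.approx(0.675, abs=5e-4)

    def test_fully_redundant_state_takes_expected_ratio(self):
        mrex = MixRatio.from_poi_fraction(0.9, 2)
        assert mr_obs((G.AB, G.AB), 739, 704, 0, mrex) == mrex
        assert chi2_weight(mr_obs((G.AB, G.AB), 739, 704, 0, mrex), mrex) == 1.0

    def test_group_sharing(self):
        """A POI inside a redundant group takes the group's per-capita share."""
        mrex = MixRatio.from_poi_fraction(0.5, 3)
        out = mr_obs((G.AB, G.AB, G.AA), 600, 400, 0, mrex)
        q_ab = 2 * 400
        assert out.fractions[0] == pytest.approx(q_ab / 2 / 1000)


class TestChi2Weight:
    def test_exact_match_is_one(self):
        for f in (0.1, 0.5, 0.94):
            assert chi2_weight((f, 1 - f), (f, 1 - f)) == 1.0

    def test_gross_mismatch_clamps_to_zero(self):
        assert chi2_weight((0.5, 0.5), (0.9, 0.1)) == 0.0

    def test_moderate_mismatch(self):
        expected = 1.0 - (0.04 / 0.9 + 0.04 / 0.1)
        assert chi2_weight((0.7, 0.3), (0.9, 0.1)) == pytest.approx(expected)

    def test_monotone_in_poi_gap(self):
        exp = (0.8, 0.2)
        gaps = [0.0, 0.05, 0.1, 0.15, 0.2]
        weights = [chi2_weight((0.8 - d, 0.2 + d), exp) for d in gaps]
        assert weights == sorted(weights, reverse=True)

    def test_zero_expected_component_floored(self):
        assert chi2_weight((1.0, 0.0), (1.0, 0.0)) == 1.0
        assert chi2_weight((0.999, 0.001), (1.0, 0.0)) == 0.0  # floored denominator


def worked_inputs():
    ev = LocusEvidence("LOC1", 739, 704)
    fr = LocusFrequencies("LOC1", "C", "T", 0.445, 0.555)
    return ev, fr


class TestContinuousLikelihood:
    def test_worked_example_with_supplied_weights(self):
        """The published three-state sum: 0.47 + 0.03 + 0.18 = 0.687."""
        ev, fr = worked_inputs()
        mrex = MixRatio.from_poi_fraction(0.94, 2)
        out = continuous_likelihood(ev, fr, [G.AB], 2, mrex, state_weights=WORKED_WEIGHTS)
        assert out.value == pytest.approx(0.687, abs=5e-3)
        # first state's product: Mendelian 2*fa*fb times h times weight 1
        first = 2 * 0.445 * 0.555 * (704 / 739) * 1.0
        assert first == pytest.approx(0.47, abs=5e-3)

    def test_single_contributor_single_state(self):
        ev, fr = worked_inputs()
        out = continuous_likelihood(ev, fr, [G.AB], 1, MixRatio((1.0,)))
        assert out.value == pytest.approx(704 / 739)  # h_state * weight(=1)

    def test_rejects_monoallelic_evidence(self):
        ev = LocusEvidence("L", 1000, 10)
        fr = LocusFrequencies("L", "C", "T", 0.5, 0.5)
        with pytest.raises(ValueError):
            continuous_likelihood(ev, fr, [G.AB], 2, MixRatio.from_poi_fraction(0.9, 2))

    @settings(max_examples=150, derandomize=True)
    @given(
        f_a=st.floats(0.05, 0.95),
        qa=st.integers(100, 5000),
        ratio=st.floats(0.06, 1.0),
        n=st.integers(1, 4),
        poi_code=st.integers(0, 3),
    )
    def test_degenerates_to_semicontinuous(self, f_a, qa, ratio, n, poi_code):
        """With h and weight pinned at 1 the three-index sum telescopes to
        the semi-continuous value of the same dispatch cell."""
        qb = max(1, int(qa * ratio))
        ev = LocusEvidence("L", qa, qb)
        if ev.evidence_class is not EvidenceClass.BIALLELIC:
            return
        fr = LocusFrequencies("L", "C", "T", f_a, 1.0 - f_a)
        pois = [] if poi_code == 3 else [G(poi_code)]
        if len(pois) > n:
            return
        cont = continuous_likelihood(
            ev, fr, pois, n, None, fixed_h=1.0, fixed_weight=1.0
        )
        semi = semicont_likelihood(EvidenceClass.BIALLELIC, pois, n, fr, 1.0)
        assert cont.value == pytest.approx(semi.value, rel=1e-12, abs=1e-15)


class TestMrEx:
    def test_closed_form_all_het_poi(self):
        """POI het at every locus with Qa = 2Qb: 2Qb/(2Qb + Qb) = 2/3."""
        loci = [f"L{i}" for i in range(5)]
        dataset = [
            (LocusEvidence(l, 800, 400), LocusFrequencies(l, "C", "T", 0.5, 0.5))
            for l in loci
        ]
        poi = ReferenceProfile("P", {l: ("C", "T") for l in loci})
        assert mr_ex(poi, dataset, 2).poi_fraction == pytest.approx(2 / 3)

    def test_balanced_het_poi_is_degenerate(self):
        loci = ["L0"]
        dataset = [
            (LocusEvidence("L0", 500, 500), LocusFrequencies("L0", "C", "T", 0.5, 0.5))
        ]
        poi = ReferenceProfile("P", {"L0": ("C", "T")})
        assert mr_ex(poi, dataset, 2).poi_fraction == pytest.approx(1.0)

    def test_no_usable_locus_is_an_error(self):
        dataset = [
            (LocusEvidence("L0", 1000, 1), LocusFrequencies("L0", "C", "T", 0.5, 0.5))
        ]
        poi = ReferenceProfile("P", {"L0": ("C", "T")})
        with pytest.raises(ValueError):
            mr_ex(poi, dataset, 2)  # the only locus is monoallelic

    def test_true_major_recovery_two_person(self):
        """On a deep 9:1 two-person mixture the major contributor's MR_ex
        lands near 0.9."""
        sim = simulate_mixture(
            SimulationConfig(L=200, n=2, ratios=(9.0, 1.0), depth=1000.0, seed=7)
        )
        est = mr_ex(sim.profiles[0], sim.dataset(), 2)
        assert est.poi_fraction == pytest.approx(0.9, abs=0.05)

    def test_false_poi_two_person_is_balanced(self):
        sim = simulate_mixture(
            SimulationConfig(L=200, n=2, ratios=(9.0, 1.0), depth=1000.0, seed=7)
        )
        false = sample_profiles(sim.panel, 1, np.random.default_rng(1234), "F")[0]
        est = mr_ex(false, sim.dataset(), 2)
        assert est.poi_fraction == pytest.approx(0.5, abs=0.07)


class TestContinuousLR:
    def test_identical_hypotheses_give_unit_lr(self, balanced_2pm):
        dataset = balanced_2pm.dataset()
        poi = balanced_2pm.profiles[0]
        rep = continuous_lr(Hypothesis(2, (poi,)), Hypothesis(2, (poi,)), dataset)
        assert rep.log10_lr == pytest.approx(0.0, abs=1e-9)
        assert (rep.per_locus["log10_lr"].abs() < 1e-9).all()

    def test_rejects_multiple_pois(self, balanced_2pm):
        dataset = balanced_2pm.dataset()
        p1, p2 = balanced_2pm.profiles
        with pytest.raises(ValueError):
            continuous_lr(Hypothesis(3, (p1, p2)), Hypothesis(3), dataset)

    def test_ceiling_audit_randomized(self):
        """Per-locus continuous LR never beats the single-source 1/P(GT)."""
        rng = np.random.default_rng(5)
        sim = simulate_mixture(
            SimulationConfig(L=120, n=2, ratios=(3.0, 1.0), depth=800.0, seed=31)
        )
        dataset = sim.dataset()
        for poi in (sim.profiles[0], sample_profiles(sim.panel, 1, rng, "F")[0]):
            rep = continuous_lr(Hypothesis(2, (poi,)), Hypothesis(2), dataset)
            assert not rep.per_locus["ceiling_flag"].any()

    def test_true_poi_log_lr_tracks_mixing_fraction(self):
        """Rank correlation between the POI's simulated fraction and the
        protocol log10 LR is positive over a ratio sweep."""
        fractions, lrs = [], []
        for i, ratios in enumerate([(1.0, 1.0), (3.0, 1.0), (9.0, 1.0), (1.0, 3.0), (1.0, 9.0)]):
            sim = simulate_mixture(
                SimulationConfig(L=133, n=2, ratios=ratios, depth=1000.0, seed=60 + i)
            )
            rep = continuous_lr(
                Hypothesis(2, (sim.profiles[0],)), Hypothesis(2), sim.dataset()
            )
            fractions.append(sim.config.fractions[0])
            lrs.append(rep.log10_lr)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(fractions, lrs)
        assert rho > 0

    def test_monoallelic_loci_use_dropout_dispatch(self):
        """A protocol mixing biallelic and monoallelic loci still computes,
        with monoallelic loci scored by the semi-continuous dropout cells."""
        loci = ["L0", "L1"]
        dataset = [
            (LocusEvidence("L0", 600, 400), LocusFrequencies("L0", "C", "T", 0.5, 0.5)),
            (LocusEvidence("L1", 1000, 10), LocusFrequencies("L1", "C", "T", 0.5, 0.5)),
        ]
        poi = ReferenceProfile("P", {l: ("C", "T") for l in loci})
        rep = continuous_lr(Hypothesis(2, (poi,)), Hypothesis(2), dataset)
        mono_row = rep.per_locus.set_index("locus_id").loc["L1"]
        assert mono_row["evidence_class"] == "monoallelic"
        assert mono_row["case_num"].startswith("E{a;bd}")


class TestMatrixTable:
    def test_row_count_and_labels(self):
        tab = matrix_table(2, 739, 704)
        assert len(tab) == 7
        assert set(tab["class"]) <= {
            "rAA+sBB",
            "rAA+sAB",
            "rAB+sBB",
            "nAB",
        }
        assert tab["unrealistic"].sum() == 2  # (AB,BB) and (BB,AB)

    def test_quantities_present_when_reads_given(self):
        tab = matrix_table(3, 600, 400)
        assert len(tab) == 25
        assert {"Q_AA", "Q_AB", "Q_BB", "h_state", "mr_state"} <= set(tab.columns)
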