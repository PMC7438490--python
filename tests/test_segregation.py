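"""Pedigree likelihoods, likelihood-ratio statistics, cross-family combination."""

import math

import numpy as np
import pytest

import coseg.segregation as seg
from coseg.errors import (
    DuplicateFamilyError,
    EnumerationGuardError,
    MendelianInconsistencyError,
)
from coseg.segregation import (
    SegregationResult,
    TransmissionModel,
    combine_lrs,
    cosegregation_lr,
    enumerate_likelihood,
    full_bayes_factor,
    pedigree_likelihood,
)
from coseg.simulate import SimulationConfig, simulate_family

from conftest import BC, OV, make_ind, make_ped


def small_random_pedigrees(seeds, max_members=11, **cfg_kw):
    """Seeded simulated pedigrees small enough for full-scope enumeration."""
    out = []
    for s in seeds:
        cfg = SimulationConfig(seed=s, n_families=1, generations=3,
                               sibship_mean=2.0, genotyping_rule="random_fraction",
                               genotyped_fraction=0.5, **cfg_kw)
        ped, _ = simulate_family(cfg, 0)
        if len(ped) <= max_members:
            out.append(ped)
    return out


class TestPedigreeLikelihood:
    def test_fully_observed_trio_is_transmission_times_priors(self, trio, flat_model, tm):
        """With all genotypes observed and a genotype-blind penetrance, the
        joint likelihood is founder-origin prior x 1/2 per transmission x
        phenotype terms."""
        ped = trio.copy()
        ped.members["dad"].genotype = seg.Genotype.CARRIER
        ped.members["mom"].genotype = seg.Genotype.NONCARRIER
        ll = pedigree_likelihood(ped, flat_model, "pathogenic", tm)
        q = tm.q
        expected = math.log(2 * q * (1 - q)) + 2 * math.log(1 - q) + math.log(0.5)
        for ind in ped:
            expected += seg.log_phenotype_likelihood(flat_model, "noncarrier", ind)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_hypotheses_coincide_under_degenerate_model(self, informative_family,
                                                        flat_model, tm):
        lp = pedigree_likelihood(informative_family, flat_model, "pathogenic", tm)
        ln = pedigree_likelihood(informative_family, flat_model, "neutral", tm)
        assert lp == pytest.approx(ln, abs=1e-12)

    def test_six_member_mixed_family_matches_enumeration(self, brca2_model, tm):
        ped = make_ped([
            make_ind("f", sex="male", censor=75),
            make_ind("m", geno="carrier", censor=72, events=[(BC, 55)]),
            make_ind("a", father="f", mother="m", geno="carrier", censor=45,
                     events=[(BC, 40)], proband=True),
            make_ind("b", father="f", mother="m", censor=50, events=[(OV, 48)]),
            make_ind("c", father="f", mother="m", geno="noncarrier", censor=47),
            make_ind("d", father="f", mother="m", sex="male", censor=52),
        ], "a")
        for hyp in ("pathogenic", "neutral"):
            assert pedigree_likelihood(ped, brca2_model, hyp, tm) == pytest.approx(
                enumerate_likelihood(ped, brca2_model, hyp, tm), abs=1e-10)

    def test_mendelian_contradiction_raises(self, brca2_model, tm):
        ped = make_ped([
            make_ind("f", sex="male", geno="noncarrier", censor=70),
            make_ind("m", geno="noncarrier", censor=70),
            make_ind("k", father="f", mother="m", geno="carrier", censor=30,
                     proband=True),
        ], "k")
        with pytest.raises(MendelianInconsistencyError):
            pedigree_likelihood(ped, brca2_model, "pathogenic", tm)


class TestEnumerationOracle:
    def test_zero_untested_single_term(self, brca2_model, tm):
        ped = make_ped([
            make_ind("f", sex="male", geno="noncarrier", censor=70),
            make_ind("m", geno="carrier", censor=68, events=[(BC, 50)]),
            make_ind("k", father="f", mother="m", geno="carrier", censor=30,
                     proband=True),
        ], "k")
        for hyp in ("pathogenic", "neutral"):
            assert enumerate_likelihood(ped, brca2_model, hyp, tm) == pytest.approx(
                pedigree_likelihood(ped, brca2_model, hyp, tm), abs=1e-12)

    def test_untested_father_two_term_sum_by_hand(self, flat_model, tm):
        """Trio with untested father: the single-origin sum has one term per
        candidate origin founder; with a genotype-blind penetrance the
        phenotype part factors out and the rest is hand-checkable."""
        ped = make_ped([
            make_ind("f", sex="male", censor=70),
            make_ind("m", geno="noncarrier", censor=68),
            make_ind("k", father="f", mother="m", geno="carrier", censor=30,
                     proband=True),
        ], "k")
        q = tm.q
        pheno = sum(seg.log_phenotype_likelihood(flat_model, "noncarrier", i)
                    for i in ped)
        # origin must be the father (mother typed noncarrier): weight x 1/2
        expected = pheno + math.log(2 * q * (1 - q) * (1 - q) ** 2 * 0.5)
        assert enumerate_likelihood(ped, flat_model, "pathogenic", tm) == pytest.approx(
            expected, abs=1e-12)

    def test_guard_refuses_large_families(self, brca2_model, tm):
        members = [make_ind("f", sex="male", censor=70), make_ind("m", censor=68)]
        members += [
            make_ind(f"k{i}", father="f", mother="m", censor=40,
                     geno="carrier" if i == 0 else "untested",
                     proband=(i == 0))
            for i in range(14)
        ]
        ped = make_ped(members, "k0")
        with pytest.raises(EnumerationGuardError):
            enumerate_likelihood(ped, brca2_model, "pathogenic", tm)

    def test_random_pedigrees_match_peeling(self, brca2_model, tm):
        peds = small_random_pedigrees(range(200, 240))
        assert len(peds) >= 15
        for ped in peds:
            for hyp in ("pathogenic", "neutral"):
                a = pedigree_likelihood(ped, brca2_model, hyp, tm)
                b = enumerate_likelihood(ped, brca2_model, hyp, tm)
                assert a == pytest.approx(b, abs=1e-10)

    def test_full_transmission_mode_matches_peeling(self, brca2_model):
        tm_full = TransmissionModel(q=1e-3, single_origin=False)
        for ped in small_random_pedigrees(range(300, 320), max_members=8):
            for hyp in ("pathogenic", "neutral"):
                a = seg._loglik(ped, brca2_model, hyp, tm_full)
                b = enumerate_likelihood(ped, brca2_model, hyp, tm_full)
                assert a == pytest.approx(b, abs=1e-10)


class TestCosegregationLr:
    def test_proband_only_genotyped_is_one(self, trio, brca2_model, tm):
        res = cosegregation_lr(trio, brca2_model, tm)
        assert res.n_genotyped == 0
        assert res.lr == pytest.approx(1.0, abs=1e-12)

    def test_proband_only_family_is_one(self, proband_only, brca2_model, tm):
        assert cosegregation_lr(proband_only, brca2_model, tm).lr == pytest.approx(1.0)

    def test_affected_carrier_relative_raises_lr(self, brca2_model, tm):
        ped = make_ped([
            make_ind("f", sex="male", censor=75),
            make_ind("m", geno="carrier", censor=72, events=[(BC, 40)]),
            make_ind("k", father="f", mother="m", geno="carrier", censor=35,
                     events=[(BC, 33)], proband=True),
        ], "k")
        res = cosegregation_lr(ped, brca2_model, tm)
        assert res.lr > 1

    def test_sign_for_unaffected_noncarrier_sib_set_by_oracle(self, brca2_model, tm):
        ped = make_ped([
            make_ind("f", sex="male", censor=70),
            make_ind("m", censor=68),
            make_ind("p", father="f", mother="m", geno="carrier", censor=40,
                     events=[(BC, 38)], proband=True),
            make_ind("s", father="f", mother="m", geno="noncarrier", censor=25),
        ], "p")
        res = cosegregation_lr(ped, brca2_model, tm)
        oracle = cosegregation_lr(ped, brca2_model, tm,
                                  _loglik_fn=enumerate_likelihood)
        assert res.lr == pytest.approx(oracle.lr, rel=1e-9)
        # a young unaffected noncarrier is only weakly informative either way
        assert 0 < res.lr

    def test_matches_enumeration_oracle_on_informative_family(
            self, informative_family, brca2_model, tm):
        res = cosegregation_lr(informative_family, brca2_model, tm)
        oracle = cosegregation_lr(informative_family, brca2_model, tm,
                                  _loglik_fn=enumerate_likelihood)
        assert res.lr == pytest.approx(oracle.lr, rel=1e-9)
        assert res.lr > 1
        assert res.n_genotyped == 8

    def test_marginalisation_consistency(self, informative_family, brca2_model, tm):
        """An extra untested individual with no phenotype information leaves
        both statistics unchanged."""
        base_c = cosegregation_lr(informative_family, brca2_model, tm).lr
        base_b = full_bayes_factor(informative_family, brca2_model, tm).lr
        extra = informative_family.copy()
        ghost = make_ind("ghost", family="FIG1", father="S1", mother="P1",
                         sex="unknown", censor=0)
        extra.members["ghost"] = ghost
        assert cosegregation_lr(extra, brca2_model, tm).lr == pytest.approx(
            base_c, rel=1e-9)
        assert full_bayes_factor(extra, brca2_model, tm).lr == pytest.approx(
            base_b, rel=1e-9)

    def test_q_invariance_under_single_origin(self, informative_family, brca2_model):
        lrs = [cosegregation_lr(informative_family, brca2_model,
                                TransmissionModel(q=q)).lr
               for q in (1e-5, 1e-4, 1e-3)]
        assert max(lrs) / min(lrs) - 1 < 0.01

    def test_obligate_carrier_counts_as_genotyped(self, brca2_model, tm):
        from coseg.pedigree import infer_obligate_carriers
        ped = make_ped([
            make_ind("gp", geno="carrier", censor=80, events=[(BC, 60)]),
            make_ind("gpf", sex="male", censor=82),
            make_ind("par", father="gpf", mother="gp", censor=55),
            make_ind("sp", sex="male", censor=56),
            make_ind("kid", father="sp", mother="par", geno="carrier",
                     censor=30, proband=True),
        ], "kid")
        inferred = infer_obligate_carriers(ped)
        assert cosegregation_lr(inferred, brca2_model, tm).n_genotyped == 2


class TestFullBayesFactor:
    def test_proband_only_family_is_one(self, proband_only, brca2_model, tm):
        assert full_bayes_factor(proband_only, brca2_model, tm).lr == pytest.approx(1.0)

    def test_degenerate_penetrance_gives_one(self, informative_family, flat_model, tm):
        assert full_bayes_factor(informative_family, flat_model, tm).lr == pytest.approx(
            1.0, abs=1e-9)

    def test_within_twofold_of_conditional_on_informative_family(
            self, informative_family, brca2_model, tm):
        c = cosegregation_lr(informative_family, brca2_model, tm).lr
        b = full_bayes_factor(informative_family, brca2_model, tm).lr
        assert 0.5 <= b / c <= 2.0


class TestCombineLrs:
    # per-family ratios reported for the ten informative study families
    TABLE = [3.44, 1.17, 3.72, 10.77, 1.03, 40.61, 1.87, 3.16, 1.13, 1.82]

    def test_reported_family_ratios_combine_to_published_total(self):
        assert combine_lrs(self.TABLE) == pytest.approx(81527, rel=0.01)

    def test_empty_is_one(self):
        assert combine_lrs([]) == 1.0

    def test_reciprocal_pair_cancels(self):
        assert combine_lrs([2.0, 0.5]) == pytest.approx(1.0)

    def test_order_invariant_and_log_additive(self):
        fwd = combine_lrs(self.TABLE)
        rev = combine_lrs(self.TABLE[::-1])
        assert fwd == pytest.approx(rev, rel=1e-12)
        assert math.log(fwd) == pytest.approx(
            sum(math.log(x) for x in self.TABLE), abs=1e-9)

    def test_duplicate_family_rejected(self):
        results = [
            SegregationResult("fam1", 2.0, "conditional_on_phenotypes", 1),
            SegregationResult("fam1", 3.0, "conditional_on_phenotypes", 2),
        ]
        with pytest.raises(DuplicateFamilyError):
            combine_lrs(results)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            combine_lrs([1.0, 0.0])


class TestTransmissionModel:
    @pytest.mark.parametrize("q", [0.0, 0.01, 0.5, -1e-4])
    def test_rare_variant_regime_enforced(self, q):
        with pytest.raises(ValueError):
            TransmissionModel(q=q)
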