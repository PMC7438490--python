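"""Shared fixtures: hand-built pedigrees and penetrance models."""

import pytest

from coseg.pedigree import (
    EventKind,
    Genotype,
    Individual,
    Pedigree,
    PhenotypeEvent,
    Sex,
)
from coseg.penetrance import PenetranceModel, load_penetrance
from coseg.segregation import TransmissionModel

BC = EventKind.BREAST_FIRST
BC2 = EventKind.BREAST_CONTRALATERAL
OV = EventKind.OVARIAN
OTH = EventKind.OTHER_IGNORED


def make_ind(iid, family="FAM", father=None, mother=None, sex="female",
             geno="untested", censor=50, events=(), proband=False):
    """Terse Individual builder: events are (kind, age[, label]) tuples."""
    evs = [PhenotypeEvent(k, a, *rest) for k, a, *rest in events]
    return Individual(iid, family, father, mother, Sex(sex), Genotype(geno),
                      evs, censor, proband)


def make_ped(members, proband_id, family="FAM"):
    return Pedigree(family, {m.individual_id: m for m in members}, proband_id)


@pytest.fixture(scope="session")
def flat_model():
    return load_penetrance("flat")


@pytest.fixture(scope="session")
def brca2_model():
    return load_penetrance("brca2_default")


@pytest.fixture(scope="session")
def constant_model():
    """Carrier ≠ noncarrier constant-hazard model with known closed forms."""
    return PenetranceModel.from_constant_hazards({
        "carrier": {"breast_first": 0.02, "breast_contralateral": 0.02, "ovarian": 0.01},
        "noncarrier": {"breast_first": 0.005, "breast_contralateral": 0.005,
                       "ovarian": 0.001},
    }, name="constant_test")


@pytest.fixture(scope="session")
def tm():
    return TransmissionModel()


@pytest.fixture
def trio():
    """Smallest valid family: two founder parents + carrier proband."""
    return make_ped([
        make_ind("dad", sex="male", censor=70),
        make_ind("mom", censor=68),
        make_ind("kid", father="dad", mother="mom", geno="carrier",
                 censor=30, proband=True),
    ], "kid")


@pytest.fixture
def informative_family():
    """Three-generation breast/ovarian cancer family ascertained through an
    affected carrier proband; emulates a real-world multiply-affected
    family: eight typed relatives (carriers with early breast/ovarian
    cancer, healthy noncarriers), untested affected members, and one tested
    noncarrier whose only event is LCIS (ignored in likelihoods)."""
    members = [
        make_ind("GF", family="FIG1", sex="male", censor=88),
        make_ind("GM", family="FIG1", geno="carrier", censor=85, events=[(BC, 81)]),
        make_ind("S1", family="FIG1", sex="male", censor=68),
        make_ind("P1", family="FIG1", father="GF", mother="GM", geno="carrier",
                 censor=62, events=[(BC, 50)]),
        make_ind("P2", family="FIG1", father="GF", mother="GM", geno="carrier",
                 censor=66, events=[(BC, 49), (BC2, 58)]),
        make_ind("P3", family="FIG1", father="GF", mother="GM", censor=70,
                 events=[(OV, 63)]),
        make_ind("P4", family="FIG1", father="GF", mother="GM", censor=72),
        make_ind("S4", family="FIG1", sex="male", censor=75),
        make_ind("PR", family="FIG1", father="S1", mother="P1", geno="carrier",
                 censor=52, events=[(BC, 44)], proband=True),
        make_ind("R1", family="FIG1", father="S1", mother="P1", geno="carrier",
                 censor=64, events=[(OV, 59)]),
        make_ind("G1", family="FIG1", father="S1", mother="P1", censor=45,
                 events=[(BC, 33)]),
        make_ind("R3", family="FIG1", father="S1", mother="P1", geno="noncarrier",
                 censor=48),
        make_ind("R4", family="FIG1", father="S1", mother="P1", sex="male",
                 geno="noncarrier", censor=50),
        make_ind("S2", family="FIG1", sex="male", censor=70),
        make_ind("C2", family="FIG1", father="S2", mother="P2", geno="noncarrier",
                 censor=40),
        make_ind("F1", family="FIG1", father="S2", mother="P2", censor=40,
                 events=[(BC, 25)]),
        make_ind("L1", family="FIG1", father="S4", mother="P4", geno="noncarrier",
                 censor=60, events=[(OTH, 55, "LCIS")]),
    ]
    return make_ped(members, "PR", family="FIG1")


@pytest.fixture
def proband_only():
    return make_ped(
        [make_ind("p", geno="carrier", censor=45, events=[(BC, 40)], proband=True)],
        "p",
    )
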