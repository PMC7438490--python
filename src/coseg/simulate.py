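"""Simulation of ascertained breast/ovarian-cancer families.

Families are generated under an explicit generative model so that every
pipeline stage can be exercised without external data:

* **structure** — a founder couple, their children, and (for three or four
  generation families) spouses marrying in and further offspring; sibship
  sizes are shifted-Poisson draws;
* **genotypes** — the variant enters through a single origin founder and is
  transmitted Mendelian; under ascertainment the designated proband (the
  founder couple's first daughter) must be a carrier;
* **phenotypes** — latent event times for first breast, ovarian and
  contralateral breast cancer are drawn from the genotype-appropriate
  penetrance table by inverse-CDF of the piecewise-constant hazards;
  censoring ages are uniform within generation-specific windows.  Under
  the *neutral* hypothesis every phenotype is drawn from the noncarrier
  table, so phenotypes are independent of genotypes;
* **ascertainment** — ``affected_carrier_proband`` requires the proband to
  be an affected carrier.  It is implemented by staged conditional
  sampling (genotype layer re-drawn until the proband carries, then the
  proband's phenotype re-drawn until affected), which is exactly
  equivalent to whole-family rejection sampling because phenotypes are
  conditionally independent across individuals given genotypes.

Each family uses its own RNG stream derived from ``(seed, family_index)``,
so studies are bit-reproducible and order-independent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .errors import AscertainmentError
from .pedigree import (
    EventKind,
    Genotype,
    Individual,
    Pedigree,
    PhenotypeEvent,
    Sex,
    write_families,
)
from .penetrance import PenetranceModel, load_penetrance
from .segregation import Hypothesis, TransmissionModel

__all__ = ["SimulationConfig", "simulate_family", "simulate_study"]

_WINDOWS = {
    # censoring-age windows (lo, hi) per generation, oldest first
    2: [(70, 90), (45, 70)],
    3: [(70, 90), (45, 70), (20, 45)],
    4: [(75, 90), (50, 75), (25, 50), (5, 25)],
}


class GenotypingRule(str, enum.Enum):
    ALL = "all"
    AFFECTED_ONLY = "affected_only"
    RANDOM_FRACTION = "random_fraction"


@dataclass
class SimulationConfig:
    seed: int
    n_families: int = 15
    hypothesis: Hypothesis = Hypothesis.PATHOGENIC
    penetrance: PenetranceModel | str = "brca2_default"
    tm: TransmissionModel = field(default_factory=TransmissionModel)
    generations: int = 3
    sibship_mean: float = 2.8  # mean of the shifted-Poisson sibship size
    sibship_max: int = 6
    p_spouse: float = 0.8  # chance a non-terminal adult marries in and reproduces
    genotyping_rule: GenotypingRule = GenotypingRule.RANDOM_FRACTION
    genotyped_fraction: float = 0.3
    ascertainment: str = "affected_carrier_proband"
    max_rejections: int = 100_000

    def __post_init__(self):
        self.hypothesis = Hypothesis(self.hypothesis)
        self.genotyping_rule = GenotypingRule(self.genotyping_rule)
        if not 2 <= self.generations <= 4:
            raise ValueError("generations must be 2-4")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if isinstance(self.penetrance, str):
            self.penetrance = load_penetrance(self.penetrance)


# ---------------------------------------------------------------------------
# latent event-time sampling

def _event_time(model: PenetranceModel, table: str, event: str, rng) -> float | None:
    """Inverse-CDF draw from the piecewise-constant hazard; None = never."""
    lam = model._hazards(table, event)
    edges = model.age_grid
    widths = np.diff(edges)
    cum = np.concatenate([[0.0], np.cumsum(lam * widths)])
    e = rng.exponential()
    if e >= cum[-1]:
        return None
    i = int(np.searchsorted(cum, e, side="right")) - 1
    return float(edges[i]) + (e - float(cum[i])) / float(lam[i])


def _draw_phenotype(ind: Individual, carrier: bool, cfg: SimulationConfig, rng,
                    censor: int) -> None:
    """Fill events for one individual given true carrier status."""
    ind.censor_age = censor
    ind.events = []
    if ind.sex is not Sex.FEMALE:
        return
    table = "carrier" if (carrier and cfg.hypothesis is Hypothesis.PATHOGENIC) else "noncarrier"
    model = cfg.penetrance
    t_bc1 = _event_time(model, table, "breast_first", rng)
    t_ov = _event_time(model, table, "ovarian", rng)
    events = []
    if t_bc1 is not None and t_bc1 < censor:
        a1 = max(1, int(t_bc1))
        events.append(PhenotypeEvent(EventKind.BREAST_FIRST, a1))
        u = _event_time(model, table, "breast_contralateral", rng)
        if u is not None and a1 + u < censor:
            events.append(PhenotypeEvent(EventKind.BREAST_CONTRALATERAL, a1 + max(0, int(u))))
    if t_ov is not None and t_ov < censor:
        events.append(PhenotypeEvent(EventKind.OVARIAN, max(1, int(t_ov))))
    ind.events = sorted(events, key=lambda e: (e.age, e.kind.value))


# ---------------------------------------------------------------------------
# family construction

def _build_structure(cfg: SimulationConfig, family_id: str, rng):
    """Create individuals (no genotypes/phenotypes); returns (members, proband_id)."""
    members: dict[str, Individual] = {}
    counter = [0]

    def new(sex: Sex, father=None, mother=None, gen=0) -> Individual:
        counter[0] += 1
        iid = f"I{counter[0]:02d}"
        ind = Individual(
            individual_id=iid, family_id=family_id,
            father_id=father, mother_id=mother, sex=sex,
        )
        ind._generation = gen  # simulation-only annotation
        members[iid] = ind
        return ind

    def sibship_size() -> int:
        return int(min(1 + rng.poisson(max(cfg.sibship_mean - 1.0, 0.0)), cfg.sibship_max))

    f0 = new(Sex.MALE, gen=0)
    m0 = new(Sex.FEMALE, gen=0)
    children = []
    for k in range(sibship_size()):
        sex = Sex.FEMALE if k == 0 else (Sex.FEMALE if rng.random() < 0.5 else Sex.MALE)
        children.append(new(sex, father=f0.individual_id, mother=m0.individual_id, gen=1))
    proband = children[0]
    proband.is_proband = True

    frontier = children
    for gen in range(2, cfg.generations):
        next_frontier = []
        for parent in frontier:
            if rng.random() >= cfg.p_spouse:
                continue
            spouse = new(Sex.FEMALE if parent.sex is Sex.MALE else Sex.MALE, gen=gen - 1)
            father = parent if parent.sex is Sex.MALE else spouse
            mother = spouse if parent.sex is Sex.MALE else parent
            for _ in range(sibship_size()):
                sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
                next_frontier.append(
                    new(sex, father=father.individual_id, mother=mother.individual_id, gen=gen)
                )
        frontier = next_frontier
    return members, proband.individual_id


def _transmit(members, founders, origin_id, rng) -> dict[str, bool]:
    """True carrier status for everyone given the origin founder."""
    carrier = {}
    order = list(members.values())
    # founders first, then repeatedly resolve children whose parents are known
    for m in order:
        if m.is_founder:
            carrier[m.individual_id] = m.individual_id == origin_id
    pending = [m for m in order if not m.is_founder]
    while pending:
        rest = []
        for m in pending:
            if m.father_id in carrier and m.mother_id in carrier:
                inherits = (carrier[m.father_id] and rng.random() < 0.5) or (
                    carrier[m.mother_id] and rng.random() < 0.5
                )
                carrier[m.individual_id] = bool(inherits)
            else:
                rest.append(m)
        if len(rest) == len(pending):
            raise RuntimeError("unresolvable pedigree order")
        pending = rest
    return carrier


def simulate_family(cfg: SimulationConfig, family_index: int = 0):
    """Generate one ascertained family; returns ``(Pedigree, truth)``.

    ``truth`` maps individual id to true carrier status.  Deterministic for
    fixed ``(cfg.seed, family_index)``.
    """
    rng = np.random.default_rng([int(cfg.seed), int(family_index)])
    family_id = f"SIM{family_index:04d}"
    members, proband_id = _build_structure(cfg, family_id, rng)
    founders = [m.individual_id for m in members.values() if m.is_founder]
    windows = _WINDOWS[cfg.generations]
    censor = {
        iid: int(rng.integers(windows[m._generation][0], windows[m._generation][1] + 1))
        for iid, m in members.items()
    }

    ascertained = cfg.ascertainment == "affected_carrier_proband"

    # genotype layer: single-origin prior over founders + Mendelian
    # transmission, conditioned (under ascertainment) on the proband carrying
    q = cfg.tm.q
    n_f = len(founders)
    w_origin = 2 * q * (1 - q) * (1 - q) ** (2 * n_f - 2)
    w_none = (1 - q) ** (2 * n_f)
    p_any_origin = n_f * w_origin / (n_f * w_origin + w_none)
    truth = None
    for _ in range(cfg.max_rejections):
        if ascertained or rng.random() < p_any_origin:
            origin = founders[int(rng.integers(n_f))]
        else:
            origin = None  # variant absent from the family
        carrier = _transmit(members, founders, origin, rng)
        if not ascertained or carrier[proband_id]:
            truth = carrier
            break
    if truth is None:
        raise AscertainmentError(
            f"{family_id}: no carrier proband after {cfg.max_rejections} genotype draws"
        )

    # phenotype layer
    for iid, ind in members.items():
        if iid == proband_id:
            continue
        _draw_phenotype(ind, truth[iid], cfg, rng, censor[iid])
    proband = members[proband_id]
    for attempt in range(cfg.max_rejections):
        _draw_phenotype(proband, truth[proband_id], cfg, rng, censor[proband_id])
        if not ascertained or proband.is_affected:
            break
    else:
        raise AscertainmentError(
            f"{family_id}: proband never affected after {cfg.max_rejections} draws"
        )

    # observed genotypes
    for iid, ind in members.items():
        tested = (
            iid == proband_id
            or cfg.genotyping_rule is GenotypingRule.ALL
            or (cfg.genotyping_rule is GenotypingRule.AFFECTED_ONLY and ind.is_affected)
            or (cfg.genotyping_rule is GenotypingRule.RANDOM_FRACTION
                and rng.random() < cfg.genotyped_fraction)
        )
        if tested:
            ind.genotype = Genotype.CARRIER if truth[iid] else Genotype.NONCARRIER
        else:
            ind.genotype = Genotype.UNTESTED
        del ind._generation

    return Pedigree(family_id=family_id, members=members, proband_id=proband_id), truth


def simulate_study(cfg: SimulationConfig, *, out_prefix=None):
    """Generate ``cfg.n_families`` independent families.

    Returns ``(pedigrees, truth_frame)`` where the frame has one row per
    individual (family, id, true carrier status, hypothesis).  With
    ``out_prefix`` the structure/phenotype file pair and a truth TSV are
    written as ``<prefix>.ped``, ``<prefix>.pheno.tsv``, ``<prefix>.truth.tsv``.
    """
    pedigrees, rows = [], []
    for i in range(cfg.n_families):
        ped, truth = simulate_family(cfg, i)
        pedigrees.append(ped)
        for iid, is_carrier in truth.items():
            rows.append({
                "FID": ped.family_id,
                "IID": iid,
                "TRUE_CARRIER": int(is_carrier),
                "HYPOTHESIS": cfg.hypothesis.value,
            })
    truth_frame = pd.DataFrame(rows)
    if out_prefix is not None:
        write_families(pedigrees, f"{out_prefix}.ped", f"{out_prefix}.pheno.tsv")
        truth_frame.to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False)
    return pedigrees, truth_frame
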