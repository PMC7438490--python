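"""Cancer-family pedigrees: data model, file I/O, validation and obligate-carrier inference.

A family is stored as a pair of plain-text files:

* a whitespace-delimited *structure* file with the classic six PED columns
  ``FID IID FATHER MOTHER SEX PROBAND`` (``0`` = missing parent; sex coded
  1 = male, 2 = female, 0 = unknown; proband flag 1/0), and
* a tab-separated *phenotype* sidecar with header
  ``FID IID GENOTYPE CENSOR_AGE BC1_AGE BC2_AGE OV_AGE OTHER`` recording the
  genotype call (``carrier`` / ``noncarrier`` / ``untested``), the censoring
  age (current age, or age at death / last follow-up) and integer ages at
  first breast cancer, contralateral breast cancer and ovarian cancer.

The split keeps the structure file usable with standard pedigree tooling
while allowing dated multi-event phenotypes, which six-column PED cannot
carry.  Ages are integer years; an event recorded at age *a* is modelled as
occurring within ``[a, a+1)``.  Tumours other than breast/ovarian (LCIS,
kidney, prostate, ...) are recorded under ``OTHER`` for reporting but never
enter any likelihood: such individuals are treated as unaffected at their
censoring age.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import (
    DuplicateIdError,
    MendelianInconsistencyError,
    PedigreeLoopError,
    PedigreeValidationError,
    ProbandError,
    UnmatchedIdError,
)

__all__ = [
    "Sex",
    "Genotype",
    "EventKind",
    "PhenotypeEvent",
    "Individual",
    "Pedigree",
    "Finding",
    "read_families",
    "write_families",
    "validate",
    "infer_obligate_carriers",
]


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Genotype(str, enum.Enum):
    CARRIER = "carrier"
    NONCARRIER = "noncarrier"
    UNTESTED = "untested"
    OBLIGATE_CARRIER = "obligate_carrier"

    @property
    def is_carrier(self) -> bool:
        return self in (Genotype.CARRIER, Genotype.OBLIGATE_CARRIER)


class EventKind(str, enum.Enum):
    BREAST_FIRST = "breast_first"
    BREAST_CONTRALATERAL = "breast_contralateral"
    OVARIAN = "ovarian"
    OTHER_IGNORED = "other_ignored"


#: The event kinds that enter the phenotype likelihood.
INFORMATIVE_KINDS = (
    EventKind.BREAST_FIRST,
    EventKind.BREAST_CONTRALATERAL,
    EventKind.OVARIAN,
)


@dataclass(frozen=True)
class PhenotypeEvent:
    kind: EventKind
    age: int
    label: str = ""  # free-text tumour label, only used for OTHER_IGNORED


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    genotype: Genotype = Genotype.UNTESTED
    events: list[PhenotypeEvent] = field(default_factory=list)
    censor_age: int = 0
    is_proband: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def event_age(self, kind: EventKind) -> int | None:
        for ev in self.events:
            if ev.kind is kind:
                return ev.age
        return None

    @property
    def informative_events(self) -> list[PhenotypeEvent]:
        return [ev for ev in self.events if ev.kind is not EventKind.OTHER_IGNORED]

    @property
    def is_affected(self) -> bool:
        """Affected = at least one informative (breast/ovarian) event."""
        return bool(self.informative_events)


@dataclass
class Pedigree:
    family_id: str
    members: dict[str, Individual]
    proband_id: str

    def __iter__(self):
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    @property
    def proband(self) -> Individual:
        return self.members[self.proband_id]

    def founders(self) -> list[Individual]:
        return [m for m in self if m.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [m for m in self if not m.is_founder]

    def children_of(self, parent_id: str) -> list[Individual]:
        return [
            m for m in self
            if parent_id in (m.father_id, m.mother_id)
        ]

    def carriers(self) -> list[Individual]:
        return [m for m in self if m.genotype.is_carrier]

    def n_genotyped_beyond_proband(self) -> int:
        return sum(
            1 for m in self
            if m.individual_id != self.proband_id
            and m.genotype is not Genotype.UNTESTED
        )

    def relationship_graph(self) -> nx.Graph:
        """Undirected graph over individuals and mating nodes.

        Each parent couple contributes one mating node linked to both
        parents and to every child of the couple.  A cycle in this graph
        is either a consanguineous mating or a marriage loop; both are
        rejected at load because the peeling engine assumes a loop-free
        pedigree.
        """
        g = nx.Graph()
        g.add_nodes_from(self.members)
        for m in self:
            if not m.is_founder:
                mating = ("mating", m.father_id, m.mother_id)
                g.add_edge(mating, m.father_id)
                g.add_edge(mating, m.mother_id)
                g.add_edge(mating, m.individual_id)
        return g

    def copy(self) -> "Pedigree":
        members = {
            iid: replace(ind, events=list(ind.events))
            for iid, ind in self.members.items()
        }
        return Pedigree(self.family_id, members, self.proband_id)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    individual_id: str
    code: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.individual_id}: {self.message}"


# ---------------------------------------------------------------------------
# parsing

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}

STRUCTURE_COLUMNS = ["FID", "IID", "FATHER", "MOTHER", "SEX", "PROBAND"]
PHENOTYPE_COLUMNS = [
    "FID", "IID", "GENOTYPE", "CENSOR_AGE", "BC1_AGE", "BC2_AGE", "OV_AGE", "OTHER",
]


def read_families(pedigree_path, phenotype_path, *, strict: bool = True) -> list[Pedigree]:
    """Load one :class:`Pedigree` per family id from the file pair.

    Parameters
    ----------
    pedigree_path, phenotype_path
        Structure file and phenotype sidecar (see module docstring).
    strict
        When true (default) any error-severity validation finding raises
        :class:`~coseg.errors.PedigreeValidationError`.

    Raises
    ------
    DuplicateIdError, UnmatchedIdError, PedigreeLoopError, ProbandError
        Named structural failures, each detected before any pedigree is
        returned.
    """
    struct = pd.read_csv(
        pedigree_path, sep=r"\s+", header=None, names=STRUCTURE_COLUMNS,
        dtype=str, comment="#",
    )
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise UnmatchedIdError(f"phenotype file lacks columns {missing}")

    pedigrees: list[Pedigree] = []
    pheno_key = {(r.FID, r.IID): r for r in pheno.itertuples(index=False)}
    seen_pheno: set[tuple[str, str]] = set()

    for fid, fam in struct.groupby("FID", sort=True):
        members: dict[str, Individual] = {}
        for row in fam.itertuples(index=False):
            if row.IID in members:
                raise DuplicateIdError(f"family {fid}: duplicate id {row.IID!r}")
            if row.SEX not in _SEX_CODES:
                raise UnmatchedIdError(
                    f"family {fid}, {row.IID}: bad sex code {row.SEX!r}"
                )
            members[row.IID] = Individual(
                individual_id=row.IID,
                family_id=fid,
                father_id=None if row.FATHER == "0" else row.FATHER,
                mother_id=None if row.MOTHER == "0" else row.MOTHER,
                sex=_SEX_CODES[row.SEX],
                is_proband=row.PROBAND == "1",
            )
        for ind in members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in members:
                    raise UnmatchedIdError(
                        f"family {fid}: {ind.individual_id} references "
                        f"unknown parent {pid!r}"
                    )
        probands = [i for i in members.values() if i.is_proband]
        if len(probands) != 1:
            raise ProbandError(
                f"family {fid}: expected exactly one proband, found {len(probands)}"
            )

        for iid, ind in members.items():
            row = pheno_key.get((fid, iid))
            if row is None:
                raise UnmatchedIdError(
                    f"family {fid}: no phenotype row for {iid!r}"
                )
            seen_pheno.add((fid, iid))
            _apply_phenotype_row(ind, row)

        ped = Pedigree(family_id=fid, members=members, proband_id=probands[0].individual_id)
        if ped.proband.genotype is not Genotype.CARRIER:
            raise ProbandError(
                f"family {fid}: proband {ped.proband_id} must be a tested carrier, "
                f"got {ped.proband.genotype.value!r}"
            )
        _reject_loops(ped)
        if strict:
            errors = [f for f in validate(ped) if f.severity == "error"]
            if errors:
                raise PedigreeValidationError(errors)
        pedigrees.append(ped)

    orphans = set(pheno_key) - seen_pheno
    if orphans:
        raise UnmatchedIdError(f"phenotype rows with no pedigree row: {sorted(orphans)}")
    return pedigrees


def _apply_phenotype_row(ind: Individual, row) -> None:
    geno = (row.GENOTYPE or "").strip().lower()
    try:
        ind.genotype = Genotype(geno)
    except ValueError:
        raise UnmatchedIdError(
            f"{ind.family_id}/{ind.individual_id}: bad genotype {row.GENOTYPE!r}"
        ) from None
    ind.censor_age = int(float(row.CENSOR_AGE))
    events = []
    for col, kind in (
        ("BC1_AGE", EventKind.BREAST_FIRST),
        ("BC2_AGE", EventKind.BREAST_CONTRALATERAL),
        ("OV_AGE", EventKind.OVARIAN),
    ):
        cell = getattr(row, col)
        if cell is not None and not pd.isna(cell) and str(cell).strip() != "":
            events.append(PhenotypeEvent(kind=kind, age=int(float(cell))))
    other = getattr(row, "OTHER")
    if other is not None and not pd.isna(other) and str(other).strip() != "":
        # format: label@age, semicolon-separated, e.g. "LCIS@55;kidney@63"
        for chunk in str(other).split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            label, _, age = chunk.partition("@")
            events.append(
                PhenotypeEvent(
                    kind=EventKind.OTHER_IGNORED,
                    age=int(float(age)) if age else ind.censor_age,
                    label=label,
                )
            )
    ind.events = sorted(events, key=lambda e: (e.age, e.kind.value))


def _reject_loops(ped: Pedigree) -> None:
    g = ped.relationship_graph()
    if not nx.is_forest(g):
        raise PedigreeLoopError(
            f"family {ped.family_id}: relationship graph contains a cycle "
            "(consanguinity or marriage loop); loop-free pedigrees only"
        )


def write_families(pedigrees: Iterable[Pedigree], pedigree_path, phenotype_path) -> None:
    """Emit the file pair; the output re-reads to an identical data model."""
    struct_lines = []
    pheno_lines = ["\t".join(PHENOTYPE_COLUMNS)]
    for ped in pedigrees:
        for ind in ped.members.values():
            struct_lines.append(" ".join([
                ped.family_id,
                ind.individual_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _SEX_OUT[ind.sex],
                "1" if ind.is_proband else "0",
            ]))
            geno = ind.genotype
            if geno is Genotype.OBLIGATE_CARRIER:
                geno = Genotype.UNTESTED  # inference output, not raw data
            cells = {
                "BC1_AGE": "", "BC2_AGE": "", "OV_AGE": "",
            }
            others = []
            for ev in ind.events:
                if ev.kind is EventKind.BREAST_FIRST:
                    cells["BC1_AGE"] = str(ev.age)
                elif ev.kind is EventKind.BREAST_CONTRALATERAL:
                    cells["BC2_AGE"] = str(ev.age)
                elif ev.kind is EventKind.OVARIAN:
                    cells["OV_AGE"] = str(ev.age)
                else:
                    others.append(f"{ev.label}@{ev.age}")
            pheno_lines.append("\t".join([
                ped.family_id, ind.individual_id, geno.value, str(ind.censor_age),
                cells["BC1_AGE"], cells["BC2_AGE"], cells["OV_AGE"],
                ";".join(others),
            ]))
    Path(pedigree_path).write_text("\n".join(struct_lines) + "\n")
    Path(phenotype_path).write_text("\n".join(pheno_lines) + "\n")


# ---------------------------------------------------------------------------
# validation

def validate(ped: Pedigree) -> list[Finding]:
    """Report every data-model invariant breach; never raises."""
    findings: list[Finding] = []

    def err(iid, code, msg):
        findings.append(Finding("error", iid, code, msg))

    def warn(iid, code, msg):
        findings.append(Finding("warning", iid, code, msg))

    for ind in ped:
        iid = ind.individual_id
        if (ind.father_id is None) != (ind.mother_id is None):
            err(iid, "single_parent", "father/mother must both be set or both missing")
        seen_kinds: set[EventKind] = set()
        for ev in ind.events:
            if ev.age <= 0:
                err(iid, "nonpositive_age", f"{ev.kind.value} at age {ev.age}")
            if ev.kind is not EventKind.OTHER_IGNORED:
                if ev.kind in seen_kinds:
                    err(iid, "duplicate_event", f"repeated {ev.kind.value}")
                seen_kinds.add(ev.kind)
        informative = ind.informative_events
        if informative and ind.censor_age < max(ev.age for ev in informative):
            err(iid, "censor_before_event", "censor age precedes an event age")
        bc1, bc2 = ind.event_age(EventKind.BREAST_FIRST), ind.event_age(EventKind.BREAST_CONTRALATERAL)
        if bc2 is not None and bc1 is None:
            err(iid, "contralateral_without_first", "contralateral event without first breast event")
        if bc1 is not None and bc2 is not None and bc2 < bc1:
            err(iid, "contralateral_order", "contralateral event precedes first breast event")
        if ind.sex is Sex.MALE and ind.event_age(EventKind.OVARIAN) is not None:
            err(iid, "male_ovarian", "ovarian event in a male")
        if ind.father_id is not None:
            father = ped.members.get(ind.father_id)
            if father is not None and father.sex is Sex.FEMALE:
                err(iid, "father_sex", f"father {ind.father_id} recorded as female")
        if ind.mother_id is not None:
            mother = ped.members.get(ind.mother_id)
            if mother is not None and mother.sex is Sex.MALE:
                err(iid, "mother_sex", f"mother {ind.mother_id} recorded as male")
        if ind.sex is Sex.UNKNOWN and informative:
            warn(iid, "unknown_sex_affected",
                 "unknown sex with breast/ovarian event; treated as female in likelihoods")
    if ped.proband.genotype is not Genotype.CARRIER:
        err(ped.proband_id, "proband_not_carrier", "proband must be a tested carrier")
    return findings


# ---------------------------------------------------------------------------
# obligate-carrier inference

def infer_obligate_carriers(ped: Pedigree) -> Pedigree:
    """Relabel untested individuals whose carrier status is forced.

    Under the single-origin assumption for a rare variant, the allele enters
    the family through one founder and descends along parent-child links.  An
    untested individual is an *obligate carrier* when every positive-
    probability genotype configuration — over all admissible origin founders,
    respecting tested genotypes — makes them a carrier.  In a loop-free
    pedigree the descent path from an origin to a carrier is unique, so the
    forced set for origin *o* is the union of the paths from *o* to each
    known carrier; the obligate set is the intersection over admissible
    origins.  Genotyped individuals are never relabelled; the operation is
    idempotent and returns a modified copy.
    """
    ped = ped.copy()
    carriers = {m.individual_id for m in ped if m.genotype.is_carrier}
    noncarriers = {m.individual_id for m in ped if m.genotype is Genotype.NONCARRIER}
    if not carriers:
        return ped

    paths = _descent_paths(ped)

    def forced_set(origin: str) -> set[str] | None:
        required: set[str] = set()
        for c in carriers:
            path = paths.get((origin, c))
            if path is None:
                return None  # origin is not an ancestor-or-self of carrier c
            required |= path
        if required & noncarriers:
            return None
        return required

    forced_sets = [s for s in (forced_set(f.individual_id) for f in ped.founders())
                   if s is not None]
    if not forced_sets:
        raise MendelianInconsistencyError(
            f"family {ped.family_id}: observed carriers share no admissible "
            "single founder origin"
        )
    obligate = set.intersection(*forced_sets) - carriers - noncarriers
    for iid in obligate:
        if ped.members[iid].genotype is Genotype.UNTESTED:
            ped.members[iid].genotype = Genotype.OBLIGATE_CARRIER
    return ped


def _descent_paths(ped: Pedigree) -> dict[tuple[str, str], set[str]]:
    """Map (ancestor, descendant) -> node set of the unique lineal path."""
    paths: dict[tuple[str, str], set[str]] = {}

    def up(iid: str) -> dict[str, set[str]]:
        # all ancestors-or-self of iid with the connecting path node sets
        out = {iid: {iid}}
        ind = ped.members[iid]
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                for anc, path in up(pid).items():
                    out[anc] = path | {iid}
        return out

    for m in ped:
        for anc, path in up(m.individual_id).items():
            paths[(anc, m.individual_id)] = path
    return paths
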