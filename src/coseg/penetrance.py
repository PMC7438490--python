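"""Age-dependent penetrance models and per-individual phenotype likelihoods.

A :class:`PenetranceModel` holds cumulative risk curves on a 5-year age grid
for three cause-specific processes per genotype (carrier / noncarrier):

* ``breast_first`` — first breast cancer, clocked from birth;
* ``ovarian`` — ovarian cancer, clocked from birth;
* ``breast_contralateral`` — second (contralateral) breast cancer, clocked
  from the age at the first breast event.

The three processes are treated as independent cause-specific hazards, so an
individual's history likelihood factorises into one term per process:
``exp(-Λ(t_event)) · λ(t_event)`` for an observed event (a density per year)
and ``exp(-Λ(t_censor))`` for a process still event-free at censoring.
Hazards are piecewise constant within grid bins, obtained from the cumulative
risk *F* by ``λ = -ln((1-F_hi)/(1-F_lo)) / width``; this makes the density
integrate exactly to ``1 - S(∞)`` on the grid.

Death from other causes enters only through the censoring age; there is no
background mortality model.  Males contribute likelihood 1 unless the model
carries a male-specific table.  Individuals whose only events are of kind
``other_ignored`` are unaffected at their censoring age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import AgeOutOfRangeError, PenetranceError
from .pedigree import EventKind, Genotype, Individual, Sex

__all__ = [
    "PenetranceModel",
    "load_penetrance",
    "hazard",
    "survival",
    "phenotype_likelihood",
    "log_phenotype_likelihood",
]

EVENTS = ("breast_first", "breast_contralateral", "ovarian")
GENOTYPE_TABLES = ("carrier", "noncarrier")

_EVENT_OF_KIND = {
    EventKind.BREAST_FIRST: "breast_first",
    EventKind.BREAST_CONTRALATERAL: "breast_contralateral",
    EventKind.OVARIAN: "ovarian",
}


def _table_key(genotype) -> str:
    """Map a genotype (enum or string) onto a penetrance table name."""
    if isinstance(genotype, Genotype):
        return "carrier" if genotype.is_carrier else "noncarrier"
    if genotype in GENOTYPE_TABLES:
        return genotype
    raise PenetranceError(f"no penetrance table for genotype {genotype!r}")


@dataclass
class PenetranceModel:
    name: str
    source: str
    age_grid: np.ndarray  # bin edges, years, strictly increasing from 0
    cum_risk: dict[str, dict[str, np.ndarray]]  # [genotype][event] -> F at edges
    cum_risk_male: dict[str, dict[str, np.ndarray]] | None = None
    _bin_hazards: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        if self.age_grid[0] != 0 or np.any(np.diff(self.age_grid) <= 0):
            raise PenetranceError("age grid must start at 0 and increase strictly")
        for tables in filter(None, (self.cum_risk, self.cum_risk_male)):
            for geno, per_event in tables.items():
                for event in EVENTS:
                    if event not in per_event:
                        raise PenetranceError(f"{geno}: missing event {event!r}")
                    f = np.asarray(per_event[event], dtype=float)
                    per_event[event] = f
                    if f.shape != self.age_grid.shape:
                        raise PenetranceError(
                            f"{geno}/{event}: {f.size} values for "
                            f"{self.age_grid.size}-point grid"
                        )
                    if f[0] != 0 or np.any(np.diff(f) < 0) or f[-1] >= 1 or np.any(f < 0):
                        raise PenetranceError(
                            f"{geno}/{event}: cumulative risk must be "
                            "non-decreasing, start at 0 and stay below 1"
                        )
        for geno in GENOTYPE_TABLES:
            if geno not in self.cum_risk:
                raise PenetranceError(f"missing genotype table {geno!r}")
        self._bin_hazards = {}

    # -- piecewise-constant hazard machinery --------------------------------

    @property
    def max_age(self) -> float:
        return float(self.age_grid[-1])

    def _hazards(self, table: str, event: str, male: bool = False) -> np.ndarray:
        key = (table, event, male)
        if key not in self._bin_hazards:
            src = self.cum_risk_male if male else self.cum_risk
            f = src[table][event]
            widths = np.diff(self.age_grid)
            surv = 1.0 - f
            self._bin_hazards[key] = -np.log(surv[1:] / surv[:-1]) / widths
        return self._bin_hazards[key]

    def hazard(self, genotype, event: str, age: float, *, male: bool = False) -> float:
        """Cause-specific hazard (per year) at ``age`` (within the grid)."""
        if not (self.age_grid[0] <= age < self.age_grid[-1]):
            raise AgeOutOfRangeError(
                f"age {age} outside grid [{self.age_grid[0]}, {self.age_grid[-1]})"
            )
        i = int(np.searchsorted(self.age_grid, age, side="right")) - 1
        return float(self._hazards(_table_key(genotype), event, male)[i])

    def cumulative_hazard(self, genotype, event: str, age: float, *, male: bool = False) -> float:
        """∫₀ᵃ λ; flat (zero hazard) beyond the last grid edge."""
        if age < 0:
            raise AgeOutOfRangeError(f"negative age {age}")
        age = min(age, self.max_age)
        lam = self._hazards(_table_key(genotype), event, male)
        edges = self.age_grid
        i = int(np.searchsorted(edges, age, side="right")) - 1
        i = min(i, lam.size - 1)
        full = float(np.dot(lam[:i], np.diff(edges)[:i]))
        return full + float(lam[i]) * (age - float(edges[i])) if age > edges[i] else full

    def survival(self, genotype, age: float) -> float:
        """P(no first informative event by ``age``): breast and ovarian compete."""
        lam = (self.cumulative_hazard(genotype, "breast_first", age)
               + self.cumulative_hazard(genotype, "ovarian", age))
        return math.exp(-lam)

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_constant_hazards(
        cls,
        rates: dict[str, dict[str, float]],
        *,
        name: str = "constant",
        source: str = "synthetic constant-hazard model",
        max_age: int = 95,
        step: int = 5,
    ) -> "PenetranceModel":
        """Build a model whose every bin hazard equals the given rate."""
        grid = np.arange(0, max_age + step, step, dtype=float)
        cum = {
            geno: {
                event: 1.0 - np.exp(-rate * grid)
                for event, rate in per_event.items()
            }
            for geno, per_event in rates.items()
        }
        return cls(name=name, source=source, age_grid=grid, cum_risk=cum)

    @classmethod
    def from_yaml(cls, path) -> "PenetranceModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                name=raw["name"],
                source=raw.get("source", ""),
                age_grid=raw["age_grid"],
                cum_risk={
                    g: {e: v for e, v in t.items()}
                    for g, t in raw["cumulative_risk"].items()
                },
                cum_risk_male=(
                    {g: dict(t) for g, t in raw["cumulative_risk_male"].items()}
                    if "cumulative_risk_male" in raw else None
                ),
            )
        except KeyError as exc:
            raise PenetranceError(f"penetrance YAML missing key {exc}") from None

    def to_yaml(self, path) -> None:
        payload = {
            "name": self.name,
            "source": self.source,
            "age_grid": [float(a) for a in self.age_grid],
            "cumulative_risk": {
                g: {e: [float(x) for x in v] for e, v in t.items()}
                for g, t in self.cum_risk.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


_BUNDLED = ("brca2_default", "flat")


def load_penetrance(name_or_path) -> PenetranceModel:
    """Load a bundled model by name (``brca2_default``, ``flat``) or any YAML path."""
    name = str(name_or_path)
    if name in _BUNDLED:
        ref = resources.files("coseg.data") / f"penetrance_{name}.yaml"
        with resources.as_file(ref) as path:
            return PenetranceModel.from_yaml(path)
    return PenetranceModel.from_yaml(name_or_path)


# ---------------------------------------------------------------------------
# module-level operation surface

def hazard(model: PenetranceModel, genotype, event: str, age: float) -> float:
    return model.hazard(genotype, event, age)


def survival(model: PenetranceModel, genotype, age: float) -> float:
    return model.survival(genotype, age)


def log_phenotype_likelihood(model: PenetranceModel, genotype, ind: Individual) -> float:
    """Log-likelihood of an individual's cancer history under a genotype.

    The history factorises over the three cause-specific processes (see
    module docstring).  Informative events must precede the censoring age;
    ``other_ignored`` events contribute nothing.
    """
    table = _table_key(genotype)

    if ind.sex is Sex.MALE or (ind.sex is Sex.UNKNOWN and not ind.is_affected):
        if model.cum_risk_male is None or ind.sex is Sex.UNKNOWN:
            return 0.0
        male = True
    else:
        male = False

    censor = float(ind.censor_age)
    a_bc1 = ind.event_age(EventKind.BREAST_FIRST)
    a_bc2 = ind.event_age(EventKind.BREAST_CONTRALATERAL)
    a_ov = ind.event_age(EventKind.OVARIAN)
    for a in (a_bc1, a_bc2, a_ov):
        if a is not None and a > censor:
            raise PenetranceError(
                f"{ind.individual_id}: event at age {a} after censor age {censor}"
            )

    def process(event: str, t_event, t_end) -> float:
        if t_event is not None:
            lam = model.hazard(table, event, float(t_event), male=male)
            cumhaz = model.cumulative_hazard(table, event, float(t_event), male=male)
            if lam <= 0.0:
                return -math.inf
            return math.log(lam) - cumhaz
        return -model.cumulative_hazard(table, event, float(t_end), male=male)

    ll = process("breast_first", a_bc1, censor)
    ll += process("ovarian", a_ov, censor)
    if a_bc1 is not None:
        # contralateral clock starts at the first breast event
        u_event = None if a_bc2 is None else a_bc2 - a_bc1
        ll += process("breast_contralateral", u_event, censor - a_bc1)
    return ll


def phenotype_likelihood(model: PenetranceModel, genotype, ind: Individual) -> float:
    """Likelihood density of the individual's history (see log variant)."""
    return math.exp(log_phenotype_likelihood(model, genotype, ind))
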