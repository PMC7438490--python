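"""In-silico prior and multifactorial combination to a posterior probability.

The physicochemical side scores a missense substitution with Grantham's
distance, built from three residue properties — atomic composition *c*,
polarity *p* and molecular volume *v*:

    D(a, b) = rho * sqrt(alpha*(c_a-c_b)^2 + beta*(p_a-p_b)^2 + gamma*(v_a-v_b)^2)

with the published weights (alpha = 1.833, beta = 0.1018, gamma = 0.000399)
and *rho* fixed by the convention that the mean distance over the 190
residue pairs is 100.  On a protein multiple alignment column the
Align-GVGD construction reduces the observed residues to their ranges in
(c, p, v) space: Grantham Variation (GV) is the Grantham-scaled diagonal of
that range box (0 for an invariant position) and Grantham Deviation (GD) is
the Grantham-scaled distance from the variant residue to the box (0 when
the variant falls inside the observed range).  The (GV, GD) pair maps to
grades C0...C65, each of which carries a calibrated prior probability of
pathogenicity.

The prior combines with the segregation likelihood ratio on the odds scale:

    posterior = prior * LR / (prior * LR + 1 - prior)

and the posterior maps to the five-tier classification used for clinical
variant reporting (class 5 definitely pathogenic > 0.99; class 4 likely
pathogenic > 0.95; class 3 uncertain; class 2 likely benign < 0.05;
class 1 benign < 0.001).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import yaml
from Bio import AlignIO, SeqIO

from .errors import ClassificationError

__all__ = [
    "GRANTHAM_PROPERTIES",
    "GranthamParams",
    "grantham_distance",
    "grantham_matrix",
    "gv_gd",
    "agvgd_class",
    "GRADES",
    "PriorTable",
    "load_prior_table",
    "prior_for",
    "posterior",
    "iarc_class",
    "frequency_report",
    "ClassificationResult",
    "read_alignment_column",
]

#: Residue atomic composition, polarity and molecular volume (c, p, v).
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

GRADES = ("C0", "C15", "C25", "C35", "C45", "C55", "C65")


def _aa(code: str) -> str:
    """Normalise a one- or three-letter residue code; reject non-standard."""
    code = str(code).strip().upper()
    if len(code) == 3:
        code = _THREE_TO_ONE.get(code, code)
    if code not in GRANTHAM_PROPERTIES:
        raise ClassificationError(f"non-standard amino acid code {code!r}")
    return code


@dataclass(frozen=True)
class GranthamParams:
    alpha: float = 1.833
    beta: float = 0.1018
    gamma: float = 0.000399
    rho: float | None = None  # None: normalise so the mean pair distance is 100

    def resolved_rho(self) -> float:
        if self.rho is not None:
            return self.rho
        mean = _mean_raw_distance(self.alpha, self.beta, self.gamma)
        return 100.0 / mean


def _raw_distance(a: str, b: str, alpha: float, beta: float, gamma: float) -> float:
    ca, pa, va = GRANTHAM_PROPERTIES[a]
    cb, pb, vb = GRANTHAM_PROPERTIES[b]
    return math.sqrt(
        alpha * (ca - cb) ** 2 + beta * (pa - pb) ** 2 + gamma * (va - vb) ** 2
    )


def _mean_raw_distance(alpha: float, beta: float, gamma: float) -> float:
    pairs = list(itertools.combinations(GRANTHAM_PROPERTIES, 2))
    return sum(_raw_distance(a, b, alpha, beta, gamma) for a, b in pairs) / len(pairs)


_DEFAULT_PARAMS = GranthamParams()
_DEFAULT_RHO = _DEFAULT_PARAMS.resolved_rho()


def grantham_distance(aa1: str, aa2: str, *, params: GranthamParams | None = None,
                      rounded: bool = True) -> float:
    """Grantham physicochemical distance; symmetric, 0 on the diagonal.

    Rounded to integer by default, matching the published matrix convention.
    """
    a, b = _aa(aa1), _aa(aa2)
    p = params or _DEFAULT_PARAMS
    rho = _DEFAULT_RHO if params is None else p.resolved_rho()
    d = rho * _raw_distance(a, b, p.alpha, p.beta, p.gamma)
    return float(round(d)) if rounded else d


def grantham_matrix(*, params: GranthamParams | None = None) -> dict[tuple[str, str], int]:
    """All 190 unordered residue-pair distances, rounded to integers."""
    return {
        (a, b): int(grantham_distance(a, b, params=params))
        for a, b in itertools.combinations(sorted(GRANTHAM_PROPERTIES), 2)
    }


# ---------------------------------------------------------------------------
# Align-GVGD

def gv_gd(column, variant: str, *, params: GranthamParams | None = None) -> tuple[float, float]:
    """Grantham Variation and Grantham Deviation for an alignment column.

    GV is the Grantham-scaled diagonal of the bounding box of the observed
    residues in (c, p, v) space (0 for an invariant column); GD is the
    Grantham-scaled distance from the variant residue to that box (0 when
    the variant lies inside the observed ranges).  Gap characters in the
    column are skipped with a warning.
    """
    residues = []
    for r in column:
        r = str(r).strip()
        if r in {"-", ".", "*", ""}:
            warnings.warn("gap in alignment column skipped", stacklevel=2)
            continue
        residues.append(_aa(r))
    if not residues:
        raise ClassificationError("alignment column contains no residues")
    var = _aa(variant)
    p = params or _DEFAULT_PARAMS
    rho = _DEFAULT_RHO if params is None else p.resolved_rho()
    props = [GRANTHAM_PROPERTIES[r] for r in residues]
    lo = [min(x[i] for x in props) for i in range(3)]
    hi = [max(x[i] for x in props) for i in range(3)]
    weights = (p.alpha, p.beta, p.gamma)
    gv = rho * math.sqrt(sum(w * (h - l) ** 2 for w, l, h in zip(weights, lo, hi)))
    vc = GRANTHAM_PROPERTIES[var]
    dev = [max(l - x, 0.0, x - h) for x, l, h in zip(vc, lo, hi)]
    gd = rho * math.sqrt(sum(w * d ** 2 for w, d in zip(weights, dev)))
    return gv, gd


def _load_thresholds(path=None) -> dict:
    if path is None:
        ref = resources.files("coseg.data") / "agvgd_thresholds.yaml"
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return raw


def agvgd_class(gv: float, gd: float, *, thresholds=None) -> str:
    """Map (GV, GD) to an Align-GVGD grade C0...C65.

    Conserved columns (GV below the cap) are graded by GD bands; variable
    columns collapse to C0.  Monotone: raising GD at fixed GV never lowers
    the grade.
    """
    if gv < 0 or gd < 0:
        raise ClassificationError("GV and GD must be non-negative")
    cfg = thresholds if isinstance(thresholds, dict) else _load_thresholds(thresholds)
    if gv > cfg["gv_cap"]:
        return "C0"
    for band in sorted(cfg["bands"], key=lambda b: -b["min_gd"]):
        if gd >= band["min_gd"]:
            return band["grade"]
    return "C0"


def read_alignment_column(alignment_path, column: int) -> list[str]:
    """Residues at 1-based ``column`` of a FASTA protein alignment."""
    try:
        aln = AlignIO.read(alignment_path, "fasta")
    except ValueError:
        # unequal lengths: fall back to per-record indexing
        aln = list(SeqIO.parse(alignment_path, "fasta"))
    length = min(len(rec.seq) for rec in aln)
    if not (1 <= column <= length):
        raise ClassificationError(
            f"column {column} outside alignment length {length}"
        )
    return [str(rec.seq[column - 1]) for rec in aln]


# ---------------------------------------------------------------------------
# priors, posterior, tiers

@dataclass(frozen=True)
class PriorTable:
    gene: str
    source: str
    priors: dict[str, float]

    def __post_init__(self):
        last = 0.0
        for grade in GRADES:
            if grade not in self.priors:
                raise ClassificationError(f"prior table missing grade {grade}")
            p = self.priors[grade]
            if not (0.0 <= p <= 1.0):
                raise ClassificationError(f"prior {p} for {grade} outside [0, 1]")
            if p < last:
                raise ClassificationError("priors must be non-decreasing with grade")
            last = p


def load_prior_table(path=None) -> PriorTable:
    """Load a grade→prior YAML; default is the bundled BRCA2 table."""
    if path is None:
        ref = resources.files("coseg.data") / "prior_brca2.yaml"
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return PriorTable(
        gene=raw.get("gene", ""),
        source=raw.get("source", ""),
        priors={k: float(v) for k, v in raw["priors"].items()},
    )


def prior_for(grade: str, table: PriorTable | None = None) -> float:
    table = table or load_prior_table()
    if grade not in table.priors:
        raise ClassificationError(f"grade {grade!r} not in prior table")
    return table.priors[grade]


def posterior(prior: float, combined_lr: float) -> float:
    """Bayes update on the odds scale; stable for very large ratios."""
    if not (0.0 < prior < 1.0):
        raise ClassificationError(f"prior must lie strictly in (0, 1), got {prior}")
    if combined_lr < 0:
        raise ClassificationError("likelihood ratio must be non-negative")
    if combined_lr == 0.0:
        return 0.0
    # work with log-odds to survive LR up to ~1e300 without overflow
    log_odds = math.log(prior) - math.log1p(-prior) + math.log(combined_lr)
    if log_odds > 0:
        return 1.0 / (1.0 + math.exp(-log_odds))
    odds = math.exp(log_odds)
    return odds / (1.0 + odds)


def iarc_class(post: float) -> int:
    """Five-tier class from the posterior probability of pathogenicity."""
    if not (0.0 <= post <= 1.0):
        raise ClassificationError(f"posterior {post} outside [0, 1]")
    if post > 0.99:
        return 5
    if post > 0.95:
        return 4
    if post >= 0.05:
        return 3
    if post >= 0.001:
        return 2
    return 1


def frequency_report(n_positive: int, n_screened: int) -> float:
    """Detection frequency as a percentage, reported to 2 decimals."""
    if n_screened <= 0:
        raise ClassificationError("screened count must be positive")
    if n_positive > n_screened or n_positive < 0:
        raise ClassificationError("positive count must lie in [0, screened]")
    return round(100.0 * n_positive / n_screened, 2)


@dataclass(frozen=True)
class ClassificationResult:
    prior: float
    combined_lr: float
    posterior: float
    iarc_class: int

    @classmethod
    def from_evidence(cls, prior: float, combined_lr: float) -> "ClassificationResult":
        post = posterior(prior, combined_lr)
        return cls(prior=prior, combined_lr=combined_lr,
                   posterior=post, iarc_class=iarc_class(post))

    def to_json_dict(self) -> dict:
        return {
            "prior": self.prior,
            "combined_lr": self.combined_lr,
            "posterior": self.posterior,
            "iarc_class": self.iarc_class,
        }
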