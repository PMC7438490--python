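"""Co-segregation likelihood ratios on cancer-family pedigrees.

The central quantity is the family likelihood ratio of "variant pathogenic"
versus "variant neutral".  Genotypes follow an autosomal-dominant rare-allele
model: founders introduce the variant (by default under a *single-origin*
restriction — at most one founder carries one copy, appropriate for a rare
allele absent from population databases), transmission is Mendelian, and
each individual's cancer history is scored with the carrier penetrance table
when they carry the variant and the hypothesis is *pathogenic*, and with the
noncarrier table otherwise.  Under the *neutral* hypothesis the variant is
transmitted but every phenotype is scored with the noncarrier table, so
phenotypes carry no information about genotypes.

Untested genotypes are summed out exactly by peeling (variable elimination
on the pedigree's genotype network — the Elston–Stewart recursion expressed
as factor elimination), in log space throughout.  A brute-force enumeration
over genotype configurations provides an independent oracle for small
families.

Two statistics are provided:

* :func:`cosegregation_lr` conditions on *all* observed phenotypes and on
  the proband's carrier genotype, so only the genotypes of relatives carry
  evidence and clinic ascertainment cancels;
* :func:`full_bayes_factor` conditions only on the proband's genotype and
  phenotype, letting relatives' phenotypes (including untested relatives')
  contribute evidence as well.

Both equal 1 for a family in which only the proband is genotyped, and
exactly 1 whenever the carrier and noncarrier penetrance tables coincide.
Per-family ratios multiply across independent families
(:func:`combine_lrs`).
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import (
    DuplicateFamilyError,
    EnumerationGuardError,
    MendelianInconsistencyError,
    PedigreeValidationError,
)
from .pedigree import Genotype, Pedigree, validate
from .penetrance import PenetranceModel, log_phenotype_likelihood

__all__ = [
    "Hypothesis",
    "TransmissionModel",
    "SegregationResult",
    "pedigree_likelihood",
    "enumerate_likelihood",
    "cosegregation_lr",
    "full_bayes_factor",
    "combine_lrs",
]


class Hypothesis(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class TransmissionModel:
    """Rare autosomal-dominant allele model.

    ``q`` is the population allele frequency (rare-variant regime enforced);
    with ``single_origin`` at most one founder carries a single copy, which
    is the appropriate restriction for a variant never seen in population
    databases.  Tested carriers are treated as heterozygous.
    """

    q: float = 1e-4
    single_origin: bool = True

    def __post_init__(self):
        if not (0.0 < self.q < 0.01):
            raise ValueError(f"allele frequency q={self.q} outside rare-variant regime (0, 0.01)")


@dataclass
class SegregationResult:
    family_id: str
    lr: float
    method: str  # "conditional_on_phenotypes" | "full_bayes_factor"
    n_genotyped: int  # genotyped (incl. obligate) individuals beyond the proband
    log_components: dict = field(default_factory=dict)

    @property
    def log10_lr(self) -> float:
        return math.log10(self.lr)

    def to_json_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "method": self.method,
            "lr": self.lr,
            "log10_lr": self.log10_lr,
            "n_genotyped": self.n_genotyped,
        }


# ---------------------------------------------------------------------------
# genotype model pieces (allele-count states 0/1/2)

_STATES = (0, 1, 2)


def _transmission_logp() -> np.ndarray:
    """log P(child | mother, father) over allele-count genotypes."""
    t = np.zeros((3, 3, 3))
    for gm in _STATES:
        for gf in _STATES:
            pm, pf = gm / 2.0, gf / 2.0
            t[gm, gf, 0] = (1 - pm) * (1 - pf)
            t[gm, gf, 1] = pm * (1 - pf) + (1 - pm) * pf
            t[gm, gf, 2] = pm * pf
    with np.errstate(divide="ignore"):
        return np.log(t)


_LOG_T = _transmission_logp()


def _evidence_states(genotype: Genotype) -> tuple[int, ...]:
    if genotype.is_carrier:
        return (1,)
    if genotype is Genotype.NONCARRIER:
        return (0,)
    return _STATES


def _phenotype_cache(ped: Pedigree, model: PenetranceModel) -> dict[str, tuple[float, float]]:
    """Per individual: (log L with carrier table, log L with noncarrier table)."""
    return {
        m.individual_id: (
            log_phenotype_likelihood(model, "carrier", m),
            log_phenotype_likelihood(model, "noncarrier", m),
        )
        for m in ped
    }


def _state_logweight(state: int, llc: float, lln: float, hypothesis: Hypothesis) -> float:
    if hypothesis is Hypothesis.NEUTRAL or state == 0:
        return lln
    return llc


def _resolve_scope(ped: Pedigree, scope) -> set[str]:
    if scope == "all":
        return set(ped.members)
    if scope == "proband":
        return {ped.proband_id}
    if scope == "none":
        return set()
    return set(scope)


def _ancestors_or_self(ped: Pedigree, iid: str) -> set[str]:
    out, stack = set(), [iid]
    while stack:
        cur = stack.pop()
        if cur in out:
            continue
        out.add(cur)
        ind = ped.members[cur]
        stack.extend(p for p in (ind.father_id, ind.mother_id) if p is not None)
    return out


# ---------------------------------------------------------------------------
# factor elimination (peeling)

def _mul(f1, f2):
    """Combine two log factors (vars tuple, ndarray) by broadcast addition."""
    v1, a1 = f1
    v2, a2 = f2
    union = v1 + tuple(v for v in v2 if v not in v1)
    a1b = a1.reshape(a1.shape + (1,) * (len(union) - len(v1)))
    # permute f2's axes into their union order, then insert singleton axes
    order = [v2.index(v) for v in union if v in v2]
    a2p = np.transpose(a2, axes=order) if v2 else a2
    shape2 = [a2.shape[v2.index(v)] if v in v2 else 1 for v in union]
    a2b = a2p.reshape(shape2)
    return union, a1b + a2b


def _eliminate_all(factors, variables) -> float:
    """Sum out every variable; return the scalar log-sum."""
    factors = list(factors)
    remaining = set(variables)
    while remaining:
        # min-degree: pick variable appearing in the smallest combined factor
        best, best_size = None, None
        for v in remaining:
            vs = set()
            for fvars, _ in factors:
                if v in fvars:
                    vs.update(fvars)
            size = len(vs)
            if best_size is None or size < best_size:
                best, best_size = v, size
        touching = [f for f in factors if best in f[0]]
        others = [f for f in factors if best not in f[0]]
        combined = touching[0]
        for f in touching[1:]:
            combined = _mul(combined, f)
        cvars, carr = combined
        axis = cvars.index(best)
        summed = logsumexp(carr, axis=axis)
        new_vars = tuple(v for v in cvars if v != best)
        others.append((new_vars, np.asarray(summed)))
        factors = others
        remaining.discard(best)
    return float(sum(f[1] for f in factors))


def _scenario_loglik(ped, domains, pheno_w, founder_fixed) -> float:
    """Log-likelihood with founder genotypes fixed to ``founder_fixed``."""
    for fid_, state in founder_fixed.items():
        if state not in domains[fid_]:
            return -math.inf
    factors = []
    variables = []
    for m in ped.nonfounders():
        iid = m.individual_id
        if len(domains[iid]) > 1:
            variables.append(iid)
        # transmission factor, with fixed / evidence-restricted axes sliced out
        fvars: list[str] = []
        arr = _LOG_T
        for pid in (m.mother_id, m.father_id, iid):
            if pid in founder_fixed:
                arr = np.take(arr, founder_fixed[pid], axis=len(fvars))
            elif len(domains[pid]) == 1:
                arr = np.take(arr, domains[pid][0], axis=len(fvars))
            else:
                arr = np.take(arr, domains[pid], axis=len(fvars))
                fvars.append(pid)
        factors.append((tuple(fvars), arr))
    variables = list(dict.fromkeys(variables))
    # phenotype terms: constants for fixed genotypes, unary factors otherwise
    const = 0.0
    for m in ped:
        iid = m.individual_id
        if iid in founder_fixed:
            const += pheno_w[iid][founder_fixed[iid]]
        elif len(domains[iid]) == 1:
            const += pheno_w[iid][domains[iid][0]]
        else:
            factors.append(((iid,), np.array([pheno_w[iid][s] for s in domains[iid]])))
    if const == -math.inf:
        return -math.inf
    return const + _eliminate_all(factors, variables)


def _loglik(
    ped: Pedigree,
    model: PenetranceModel,
    hypothesis: Hypothesis,
    tm: TransmissionModel,
    *,
    geno_scope="all",
    pheno_scope="all",
    pheno_cache=None,
) -> float:
    hypothesis = Hypothesis(hypothesis)
    geno_ids = _resolve_scope(ped, geno_scope)
    pheno_ids = _resolve_scope(ped, pheno_scope)
    cache = pheno_cache if pheno_cache is not None else _phenotype_cache(ped, model)

    domains = {}
    for m in ped:
        iid = m.individual_id
        if iid in geno_ids:
            domains[iid] = _evidence_states(m.genotype)
        else:
            domains[iid] = _STATES

    pheno_w = {}
    for m in ped:
        iid = m.individual_id
        if iid in pheno_ids:
            llc, lln = cache[iid]
            pheno_w[iid] = {s: _state_logweight(s, llc, lln, hypothesis) for s in _STATES}
        else:
            pheno_w[iid] = {s: 0.0 for s in _STATES}

    founders = ped.founders()
    q = tm.q
    if tm.single_origin:
        n_f = len(founders)
        log_w_origin = math.log(2 * q * (1 - q)) + (2 * n_f - 2) * math.log(1 - q)
        log_w_none = 2 * n_f * math.log(1 - q)
        # a hard carrier observation restricts admissible origins to its ancestry
        carrier_ids = [iid for iid, dom in domains.items() if dom == (1,)]
        admissible = set(ped.members)
        for iid in carrier_ids:
            admissible &= _ancestors_or_self(ped, iid)
        terms = []
        for origin in founders:
            if carrier_ids and origin.individual_id not in admissible:
                continue
            fixed = {f.individual_id: (1 if f is origin else 0) for f in founders}
            terms.append(log_w_origin + _scenario_loglik(ped, domains, pheno_w, fixed))
        if not carrier_ids:
            fixed = {f.individual_id: 0 for f in founders}
            terms.append(log_w_none + _scenario_loglik(ped, domains, pheno_w, fixed))
        return float(logsumexp(terms)) if terms else -math.inf
    # full model: independent Hardy-Weinberg founder priors
    log_hwe = np.log([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    factors = []
    variables = []
    domains = dict(domains)
    const = 0.0
    for f in founders:
        iid = f.individual_id
        dom = domains[iid]
        if len(dom) == 1:
            const += float(log_hwe[dom[0]]) + pheno_w[iid][dom[0]]
        else:
            factors.append(((iid,), np.array([log_hwe[s] + pheno_w[iid][s] for s in dom])))
            variables.append(iid)
    for m in ped.nonfounders():
        iid = m.individual_id
        fvars, arr = [], _LOG_T
        for pid in (m.mother_id, m.father_id, iid):
            if len(domains[pid]) == 1:
                arr = np.take(arr, domains[pid][0], axis=len(fvars))
            else:
                arr = np.take(arr, domains[pid], axis=len(fvars))
                fvars.append(pid)
        factors.append((tuple(fvars), arr))
        if len(domains[iid]) > 1:
            variables.append(iid)
            factors.append(((iid,), np.array([pheno_w[iid][s] for s in domains[iid]])))
        else:
            const += pheno_w[iid][domains[iid][0]]
    variables = list(dict.fromkeys(variables))
    return const + _eliminate_all(factors, variables)


# ---------------------------------------------------------------------------
# public operations

def _check_ped(ped: Pedigree) -> None:
    errors = [f for f in validate(ped) if f.severity == "error"]
    if errors:
        raise PedigreeValidationError(errors)


def pedigree_likelihood(
    ped: Pedigree,
    model: PenetranceModel,
    hypothesis,
    tm: TransmissionModel = TransmissionModel(),
) -> float:
    """Joint log-likelihood of observed genotypes and phenotypes by peeling.

    Founder genotypes follow the transmission model's prior (single-origin
    restriction or Hardy-Weinberg), transmission is Mendelian, and each
    individual's phenotype is scored under their (possibly summed-out)
    genotype.  Raises :class:`MendelianInconsistencyError` when the observed
    genotypes are impossible under Mendelian transmission.
    """
    _check_ped(ped)
    ll = _loglik(ped, model, hypothesis, tm)
    if ll == -math.inf:
        raise MendelianInconsistencyError(
            f"family {ped.family_id}: observed genotypes have zero probability"
        )
    return ll


def enumerate_likelihood(
    ped: Pedigree,
    model: PenetranceModel,
    hypothesis,
    tm: TransmissionModel = TransmissionModel(),
    *,
    max_untested: int = 12,
    geno_scope="all",
    pheno_scope="all",
) -> float:
    """Brute-force oracle: exact sum over genotype configurations.

    Shares the contract of :func:`pedigree_likelihood` but enumerates every
    configuration of untested genotypes directly, refusing families with
    more than ``max_untested`` untested members.  Independent of the peeling
    code path by construction.
    """
    hypothesis = Hypothesis(hypothesis)
    geno_ids = _resolve_scope(ped, geno_scope)
    pheno_ids = _resolve_scope(ped, pheno_scope)
    members = list(ped)
    states = {}
    for m in members:
        states[m.individual_id] = (
            _evidence_states(m.genotype) if m.individual_id in geno_ids else None
        )
    untested = [m.individual_id for m in members if states[m.individual_id] is None
                or len(states[m.individual_id]) > 1]
    # founders are fixed per origin scenario under single origin, so only
    # untested nonfounders contribute to the combinatorial load
    load = [iid for iid in untested if not ped.members[iid].is_founder] \
        if tm.single_origin else untested
    if len(load) > max_untested:
        raise EnumerationGuardError(
            f"{len(load)} untested members exceed the enumeration guard "
            f"({max_untested})"
        )

    cache = _phenotype_cache(ped, model)

    def pheno_p(iid: str, g: int) -> float:
        if iid not in pheno_ids:
            return 1.0
        llc, lln = cache[iid]
        return math.exp(_state_logweight(g, llc, lln, hypothesis))

    founders = [m.individual_id for m in members if ped.members[m.individual_id].is_founder]
    nonfounders = [m for m in members if not m.is_founder]
    q = tm.q

    def config_prob(assign: dict[str, int], founder_prior) -> float:
        p = 1.0
        for fid_ in founders:
            p *= founder_prior(fid_, assign[fid_])
        for m in nonfounders:
            gm, gf, gc = assign[m.mother_id], assign[m.father_id], assign[m.individual_id]
            pm, pf = gm / 2.0, gf / 2.0
            if gc == 0:
                p *= (1 - pm) * (1 - pf)
            elif gc == 1:
                p *= pm * (1 - pf) + (1 - pm) * pf
            else:
                p *= pm * pf
            if p == 0.0:
                return 0.0
        for m in members:
            p *= pheno_p(m.individual_id, assign[m.individual_id])
        return p

    total = 0.0
    if tm.single_origin:
        # one scenario per candidate origin founder, plus the no-variant one;
        # descendants can only be het, so free states are {0, 1}
        n_f = len(founders)
        w_origin = 2 * q * (1 - q) * (1 - q) ** (2 * n_f - 2)
        w_none = (1 - q) ** (2 * n_f)
        free = [iid for iid in untested if iid not in founders]
        scenarios = [(f, w_origin) for f in founders] + [(None, w_none)]
        for origin, weight in scenarios:
            base = {}
            ok = True
            for fid_ in founders:
                g = 1 if fid_ == origin else 0
                allowed = states[fid_]
                if allowed is not None and g not in allowed:
                    ok = False
                    break
                base[fid_] = g
            if not ok:
                continue
            fixed_nonfounders = {
                m.individual_id: states[m.individual_id][0]
                for m in nonfounders
                if states[m.individual_id] is not None and len(states[m.individual_id]) == 1
            }
            for combo in itertools.product((0, 1), repeat=len(free)):
                assign = dict(base)
                assign.update(fixed_nonfounders)
                assign.update(zip(free, combo))
                total += weight * config_prob(assign, lambda fid_, g: 1.0)
    else:
        hwe = ((1 - q) ** 2, 2 * q * (1 - q), q * q)
        fixed = {iid: s[0] for iid, s in states.items() if s is not None and len(s) == 1}
        free = [iid for iid in untested]
        for combo in itertools.product(_STATES, repeat=len(free)):
            assign = dict(fixed)
            assign.update(zip(free, combo))
            total += config_prob(assign, lambda fid_, g: hwe[g])
    if total <= 0.0:
        return -math.inf
    return math.log(total)


def _conditional_lr(ped, model, tm, pheno_scope, method, _loglik_fn=None) -> SegregationResult:
    """Shared engine: genotype-evidence LR conditioned on a phenotype scope."""
    _check_ped(ped)
    fn = _loglik_fn or _loglik
    cache = _phenotype_cache(ped, model)
    kw = dict(tm=tm, pheno_cache=cache) if fn is _loglik else dict(tm=tm)
    terms = {}
    for hyp in Hypothesis:
        la = fn(ped, model, hyp, geno_scope="all", pheno_scope=pheno_scope, **kw)
        lm = fn(ped, model, hyp, geno_scope="proband", pheno_scope=pheno_scope, **kw)
        if math.isinf(la):
            raise MendelianInconsistencyError(
                f"family {ped.family_id}: observed genotypes have zero probability"
            )
        terms[hyp] = (la, lm)
    log_lr = (terms[Hypothesis.PATHOGENIC][0] - terms[Hypothesis.PATHOGENIC][1]) - (
        terms[Hypothesis.NEUTRAL][0] - terms[Hypothesis.NEUTRAL][1]
    )
    return SegregationResult(
        family_id=ped.family_id,
        lr=math.exp(log_lr),
        method=method,
        n_genotyped=ped.n_genotyped_beyond_proband(),
        log_components=_audit(ped, cache, terms),
    )


def cosegregation_lr(
    ped: Pedigree,
    model: PenetranceModel,
    tm: TransmissionModel = TransmissionModel(),
    *,
    _loglik_fn=None,
) -> SegregationResult:
    """Likelihood ratio of relatives' genotypes given typed members' phenotypes.

    ``LR = P(relatives' genotypes | phenotypes of genotyped members, proband
    carrier, pathogenic) / P(same | neutral)``.  The method's inputs are the
    ages, sexes, cancer histories and genotypes of the *typed* family
    members (obligate carriers included); untested relatives contribute
    transmission structure only.  Conditioning on the proband's carrier
    status and phenotype cancels clinic ascertainment: the proband carries
    no direct evidence and a family with nobody else genotyped scores
    exactly 1.
    """
    typed = {
        m.individual_id for m in ped
        if m.genotype is not Genotype.UNTESTED or m.individual_id == ped.proband_id
    }
    return _conditional_lr(ped, model, tm, typed, "conditional_on_phenotypes",
                           _loglik_fn)


def full_bayes_factor(
    ped: Pedigree,
    model: PenetranceModel,
    tm: TransmissionModel = TransmissionModel(),
) -> SegregationResult:
    """Full-likelihood Bayes factor, conditioned on the proband's own data.

    ``BF = P(phenotypes, genotypes | variant causal) / P(phenotypes,
    genotypes | genotype independent of phenotype)``, both conditioned on
    the proband's carrier genotype and phenotype.  In the independence
    (null) model the typed variant segregates as a neutral Mendelian
    marker while the phenotypes keep their high-risk marginal
    distribution — the family is a cancer family under either hypothesis —
    so the joint null factorises into the genotype-only likelihood times
    the genotype-marginalised phenotype likelihood, and the ratio reduces
    to the genotype-evidence LR conditioned on *all* phenotypes.  This is
    where it differs from :func:`cosegregation_lr`: untested relatives'
    phenotypes inform the genotype distribution as well.
    """
    return _conditional_lr(ped, model, tm, "all", "full_bayes_factor")


def _audit(ped, cache, terms) -> dict:
    out = {
        "per_individual": {
            iid: {"log_lik_carrier_table": llc, "log_lik_noncarrier_table": lln}
            for iid, (llc, lln) in cache.items()
        }
    }
    for hyp, (la, lb) in terms.items():
        out[f"loglik_joint_{hyp.value}"] = la
        out[f"loglik_conditioning_{hyp.value}"] = lb
    return out


def combine_lrs(results) -> float:
    """Product of per-family likelihood ratios (independent families).

    Accepts :class:`SegregationResult` objects or bare positive numbers;
    duplicate family ids raise :class:`DuplicateFamilyError`.  An empty
    input gives 1.
    """
    seen: set[str] = set()
    logs = []
    for r in results:
        if isinstance(r, SegregationResult):
            if r.family_id in seen:
                raise DuplicateFamilyError(
                    f"family {r.family_id} appears more than once; "
                    "per-family ratios must be independent"
                )
            seen.add(r.family_id)
            lr = r.lr
        else:
            lr = float(r)
        if lr <= 0:
            raise ValueError(f"likelihood ratio must be positive, got {lr}")
        logs.append(math.log(lr))
    return math.exp(math.fsum(logs))
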