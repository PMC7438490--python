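# Methods

This note documents the models behind `coseg`, the choices made where the
design was genuinely open, and what the bundled tests do and do not
establish.

## Data model

A family is a loop-free pedigree (consanguinity and marriage loops are
rejected at load: the peeling engine performs no loop breaking). Each
individual carries a genotype call (`carrier`, `noncarrier`, `untested`, or
inferred `obligate_carrier`), a censoring age (current age, or age at
death/last follow-up — the format requires an explicit censoring age even
for deceased untested relatives), and dated cancer events: first breast,
contralateral breast, ovarian, plus free-text "other" tumours. Ages are
integer years; an event recorded at age *a* is modelled as occurring in
[*a*, *a*+1). Other tumours (LCIS, kidney, prostate, …) are kept for
reporting but never enter a likelihood: such individuals are treated as
unaffected at their censoring age. Individuals of unknown sex with a
breast/ovarian event are scored with the female tables; males contribute
likelihood 1 unless a male-specific table is supplied (none is bundled).

Obligate carriers are untested individuals forced to carry under
single-origin Mendelian transmission: the implementation intersects, over
every admissible origin founder, the union of lineal descent paths from
that origin to each known carrier. Only individuals carried in *every*
positive-probability configuration are relabelled; in particular, when two
untested grandparents could each be the origin, neither is forced. Obligate
carriers are treated downstream exactly like tested carriers.

## Penetrance

A penetrance model is a pair of cumulative-risk tables (carrier /
noncarrier) on a 5-year age grid (0–95) for three cause-specific
processes: first breast cancer and ovarian cancer clocked from birth, and
contralateral breast cancer clocked from the first breast event. Bin
hazards follow from the cumulative risk *F* by
λ = −ln((1−F_hi)/(1−F_lo))/width, giving densities that integrate exactly
to 1 − S(∞) (verified numerically to 1e-6). The three processes are
independent given genotype, so a history's likelihood factorises into one
survival/density term per process; death from other causes enters only
through censoring (no background mortality model).

Two models ship as YAML and are user-replaceable:

- `brca2_default` — carrier risks patterned on published BRCA2 penetrance
  (~45% breast / ~11% ovarian by age 70, contralateral ≈2%/yr), noncarrier
  risks on registry-style population incidence (~9% / ~1% by 70,
  contralateral ≈0.5%/yr). The grid extends to 95 because real family data
  contain events in the 80s.
- `flat` — carrier ≡ noncarrier with constant hazards (breast 0.02/yr,
  contralateral 0.02/yr, ovarian 0.01/yr). Every likelihood ratio is
  exactly 1 under this model, which anchors the degenerate-case tests.

## Transmission and peeling

Genotypes are variant-allele counts {0, 1, 2} under autosomal-dominant
inheritance; tested carriers are treated as heterozygous (the rare-variant
regime 0 < q < 0.01 is enforced). The default transmission model is
*single origin* with q = 1e-4: at most one founder introduces one copy,
appropriate for a variant absent from population databases. The likelihood
sums one peeling pass per candidate origin founder (founder genotypes
fixed, untested descendants summed out by exact factor elimination in log
space); the non-restricted mode instead uses independent Hardy–Weinberg
founder priors with full 3-state peeling. Observed genotypes impossible
under Mendelian transmission raise a named inconsistency error rather than
returning −∞ silently.

Because every admissible origin has the same prior weight, q cancels
exactly in any statistic conditioned on the proband's carrier status: the
measured LR drift across q ∈ [1e-5, 1e-3] is zero to machine precision.

## The two likelihood-ratio statistics

Both statistics condition on the proband's carrier genotype and phenotype,
so clinic ascertainment cancels, the proband contributes no direct
evidence, and a family with nobody else genotyped scores exactly 1.

- **Conditional co-segregation LR** (`cosegregation_lr`): the probability
  of the relatives' observed genotypes given the phenotypes of the *typed*
  members, pathogenic versus neutral. Its inputs are exactly the current
  age, sex, ages of onset and genotype of each typed family member;
  untested relatives contribute transmission structure only. Under the
  neutral hypothesis genotypes are independent of phenotypes, which gives
  the statistic an exact martingale property: over genotype realisations
  simulated under the null, E[LR] = 1.
- **Full-likelihood Bayes factor** (`full_bayes_factor`): the joint
  probability of phenotypes and genotypes under "variant causal" versus a
  null in which the typed variant segregates as a neutral Mendelian marker
  while phenotypes keep their high-risk marginal distribution (the family
  is a cancer family under either hypothesis). The ratio reduces to the
  genotype-evidence LR conditioned on *all* phenotypes, so untested
  relatives' cancer histories inform their genotype distribution — the
  only difference from the conditional method. Choosing a population-risk
  phenotype null instead would fold the entire family-history evidence
  into the statistic and inflate it by orders of magnitude on
  multiply-affected families; that variant is deliberately not offered.

The treatment of untested individuals' phenotypes is the one genuinely
open convention in this class of methods; fixing the conditional method on
typed members and the Bayes factor on everyone brackets the choice, and
the two agree within 2-fold on well-typed informative families (measured
1.13-fold on the bundled multiply-affected fixture), mirroring the
cross-checking role the full-likelihood method plays in practice.

Phenocopies need no special casing: an affected tested noncarrier is
scored by the noncarrier table and simply lowers the LR. Per-family LRs
multiply across independent families (duplicate family ids are rejected);
results are reported as LR with log10 alongside, with per-individual log
contributions available for audit.

## In-silico prior

Grantham's distance is evaluated from the published composition, polarity
and molecular-volume values with weights α = 1.833, β = 0.1018,
γ = 0.000399, scaled so the mean distance over the 190 residue pairs is
exactly 100 (ρ ≈ 50.790). This normalisation reproduces the standard
integer matrix (Gly–Val 109, Leu–Ile 5, Cys–Trp 215); the whole 190-pair
matrix is regenerated at run time and checked against a frozen fixture.
GV/GD use the simple range construction in (c, p, v) space. Grades follow
a config-driven rule: columns with GV ≤ 61.3 are graded by GD bands at
15/25/35/45/55/65; more variable columns collapse to C0. The exact
behaviour of the published classifier at intermediate GV is not
reproducible offline, so the boundary file is deliberately user-replaceable
config rather than code. The bundled BRCA2 prior table anchors C65 at 0.81
per the published calibration of Align-GVGD grades against classified
BRCA missense substitutions, with non-decreasing priors for lower grades;
it is likewise a replaceable YAML citing its source.

The posterior is a log-odds-scale Bayes update (stable for LR up to
1e300), and the five-tier class uses the published posterior bands:
class 5 > 0.99, class 4 (0.95, 0.99], class 3 [0.05, 0.95], class 2
[0.001, 0.05), class 1 < 0.001.

## Synthetic families

The generator emulates multi-generation breast/ovarian-cancer families
ascertained through an affected carrier proband. Structure: a founder
couple, shifted-Poisson sibships (mean 2.8, capped at 6), spouses marrying
in with probability 0.8, 2–4 generations; the proband is the founder
couple's first daughter. Censoring ages are uniform in generation-specific
windows (e.g. 70–90 / 45–70 / 20–45 for three generations). Genotypes
descend from a single origin founder; phenotypes are drawn from the
genotype-appropriate table by inverse-CDF of the piecewise-constant
hazards (noncarrier table for everyone under the neutral hypothesis).
Ascertainment is implemented by staged conditional sampling — the genotype
layer is re-drawn until the proband carries, then the proband's phenotype
until affected — which is exactly equivalent to whole-family rejection
because phenotypes are conditionally independent across individuals given
genotypes; this is what makes the null-calibration test an exact check
rather than an approximation. Each family consumes an RNG stream derived
from (seed, family index), so studies are bit-reproducible and
order-independent. Genotyping rules: everyone, affected-only, or an
independent random fraction (default 0.3, giving a mix of informative and
proband-only families comparable to a real recurrent-variant study).

The generator reproduces the configured allele frequency among founders
when ascertainment is disabled, and under the pathogenic default the mean
carrier age at first breast cancer lands in the low-to-mid 40s with
noncarrier onsets later — consistent with a high-risk BRCA2-like allele.
What the simulator does *not* model: population demography, de novo
variants, genotyping error, half-sibs and loops, male breast cancer, and
real cohort/calendar effects; passing tests therefore validate the
inference machinery under its own generative assumptions, not the
realism of any particular penetrance table for a given clinical cohort.

## Problem sizes and numerics

The randomized oracle suite checks peeling against brute-force enumeration
(exact sum over genotype configurations, an independent code path) to
1e-10 in log-likelihood on 100 seeded pedigrees with ≤ 12 untested
members; the null calibration uses 10,000 neutral families (mean LR within
3 Monte-Carlo SE of 1) and the power check 1,500 pathogenic families —
sizes chosen to keep the whole suite around a minute on one CPU while
leaving the Monte-Carlo bands tight. All pedigree arithmetic is in log
space; zero-probability configurations surface as named errors, and
enumeration refuses families beyond its combinatorial guard rather than
running unbounded.

## Known limitations

- Loop-free pedigrees only; no loop transformation is attempted.
- No polygenic or frailty background; relatives' risks are independent
  given genotype, which understates familial correlation from other causes.
- The bundled penetrance curves are package defaults in the spirit of
  published BRCA2 estimates, not a specific published table; per-family
  LRs on real data depend on this choice and should be recomputed with the
  user's preferred table (a YAML swap).
- The Align-GVGD grade boundaries at intermediate GV are a simplification
  of the published classifier (see above).
- Priors for grades other than C65 are calibration-table entries that the
  user can and should replace for genes other than BRCA2.
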