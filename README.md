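# coseg

Quantitative classification of rare cancer-predisposition variants from
family data. `coseg` implements the multifactorial pieces needed to move a
missense variant of uncertain significance (VUS) in a gene such as *BRCA2*
toward a definitive class: exact **co-segregation likelihood ratios** on
breast/ovarian-cancer pedigrees with age-dependent penetrance, their
combination across independent families, a calibrated **in-silico prior**
from Grantham/Align-GVGD physicochemical conservation scores, and the
resulting **posterior probability of pathogenicity** with its five-tier
(IARC-style) class. A seeded simulator of ascertained cancer families makes
every stage testable without patient data.

It is written for clinical-genetics and statistical-genetics practitioners
who have pedigree and genotype data for a recurrent variant and want a
reproducible, auditable segregation analysis.

## The statistics

For one family with observed genotypes *G* (the proband is always a tested
carrier) and phenotypes *Y* (ages at first/contralateral breast and ovarian
cancer, censoring ages), the co-segregation likelihood ratio is

    LR = P(G | Y_typed, G_proband, variant pathogenic)
         ───────────────────────────────────────────────
         P(G | Y_typed, G_proband, variant neutral)

computed by Elston–Stewart peeling (exact variable elimination over
untested genotypes) under a rare autosomal-dominant single-origin
transmission model. Under "pathogenic", carriers' phenotypes follow the
carrier penetrance table; under "neutral", everyone follows the noncarrier
table. Conditioning on the proband's own genotype and phenotype cancels
clinic ascertainment, so a family with nobody else genotyped scores exactly
LR = 1. A full-likelihood Bayes factor variant additionally lets untested
relatives' phenotypes inform their genotype distribution; the two agree
closely on well-typed families.

Phenotype likelihoods treat first breast, ovarian and contralateral breast
cancer as independent cause-specific processes with piecewise-constant
hazards derived from cumulative-risk tables (5-year bins); an observed
event at age *a* contributes `exp(-Λ(a))·λ(a)` and an event-free process
contributes `exp(-Λ(censor))`.

LRs multiply across independent families, and the posterior follows by a
Bayes update on the odds scale:

    posterior = prior · LR_combined / (prior · LR_combined + 1 − prior)

with the prior taken from the Align-GVGD grade (C0…C65) of the substitution:
Grantham Variation (spread of residues observed across species in
composition/polarity/volume space) and Grantham Deviation (distance of the
variant residue from that observed range), on Grantham's scale where the
mean inter-residue distance is 100.

## Worked example

Simulate a 10-family study under the pathogenic hypothesis and classify it
with the C65 in-silico prior:

```sh
$ coseg simulate --seed 7 --n-families 10 --out-prefix demo
wrote demo.ped, demo.pheno.tsv, demo.truth.tsv

$ coseg classify --pedigree demo.ped --phenotypes demo.pheno.tsv --grade C65
SIM0000   LR=1.772    log10=+0.248   n_genotyped=4
SIM0001   LR=4.243    log10=+0.628   n_genotyped=5
...
SIM0009   LR=1.329    log10=+0.124   n_genotyped=5
combined LR   14.6908
prior         0.81
posterior     0.984284
IARC class    4
```

Each family line is its likelihood ratio of pathogenicity versus
neutrality given that family's genotypes; the combined LR (≈14.7) is their
product, and with the 0.81 prior the posterior 0.984 lands in class 4
(likely pathogenic) — ten families of this informativeness are not quite
enough for class 5, which requires posterior > 0.99.

The in-silico branch alone, for a valine substituting a glycine invariant
across a 12-species protein alignment:

```sh
$ coseg agvgd --alignment aln.fasta --column 4 --variant V
GV      0.00
GD      108.93
grade   C65
prior   0.81
```

GV = 0 marks the invariant column; GD ≈ 109 is the Gly–Val Grantham
distance; C65 is the most-deleterious grade and carries a 0.81 prior
probability of pathogenicity in the bundled BRCA2 calibration table.

The same operations are available as a library
(`coseg.cosegregation_lr`, `coseg.combine_lrs`, `coseg.posterior`, …);
`coseg calibrate` runs the null-calibration simulation (mean LR over
neutral families ≈ 1).

## Layout

- `coseg.pedigree` — data model, PED-style structure + phenotype TSV I/O,
  validation, obligate-carrier inference
- `coseg.penetrance` — cumulative-risk tables (YAML), hazards, survival,
  per-individual history likelihoods
- `coseg.segregation` — peeling, enumeration oracle, the two LR
  statistics, cross-family combination
- `coseg.classification` — Grantham matrix, GV/GD, grades, priors,
  posterior, five-tier class, screening frequency
- `coseg.simulate` — seeded generator of ascertained families under either
  hypothesis
- `coseg.cli` — `coseg classify / agvgd / simulate / calibrate / validate`

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
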