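# sociogwas

Direct and social genetic effects for group-housed animals: variance
components by AI-REML, pseudo-phenotypes, and single-/multi-locus genome
scans — with a synthetic-data generator that reproduces the statistical
structure the analysis assumes, so the whole pipeline is testable without
any external data.

## The problem

When pigs are finished in pens, an animal's growth depends not only on its
own genotype (the **direct genetic effect**, DGE) but also on the genotypes
of its pen-mates (the **social** or indirect **genetic effect**, SGE —
think competition at the feeder, tail biting, group calm).  Ignoring SGE
misestimates genetic variance and hides a heritable pathway that selection
could use.  This package implements the two-stage analysis used to study
such traits:

1. **Variance components and breeding values.**  For animal *i* in a pen of
   *n* animals,

       Y = Xb + Z_D a_D + Z_S a_S + Wl + Vg + e

   with fixed effects (sex, tested year-month), direct breeding values
   `a_D`, social breeding values `a_S` (row *i* of `Z_S` marks *i*'s
   pen-mates; an animal's own social value never enters its own record),
   random litter `l` and pen `g` effects.  `(a_D, a_S)` have covariance
   `G0 ⊗ A` with `A` the pedigree numerator relationship matrix.  The six
   components are estimated by average-information REML; the fit yields
   BLUPs, classical heritability h² = σ²_Ad/σ²_P, the total heritable
   variance σ²_TBV = σ²_Ad + 2(n−1)σ_Ads + (n−1)²σ²_As, total heritability
   T² = σ²_TBV/σ²_TP, and the direct-social genetic correlation r_ADS.

2. **Genome scans on pseudo-phenotypes.**  Per-animal responses
   `â_D + ê` (for DGE) or `Z_S â_S + ê` (for SGE) are scanned over
   QC-passed SNPs, single-locus (mixed model with a genomic relationship
   kinship, Wald test, thresholds 5×10⁻⁸ / 5×10⁻⁷) and multi-locus
   (screen at P ≤ 0.005, then joint shrinkage estimation with LOD ≥ 3
   retention, reporting QTN effects and percent variance explained).
   Significant SNPs are grouped into top-SNP-anchored regions and annotated
   with genes within ±20 kb.

It is aimed at quantitative geneticists and animal-breeding researchers who
want a transparent, fully tested reference implementation of the social
animal model and its genome-scan follow-up.

## Worked example

Running `python examples/02_simulate_and_fit.py` (1,500 simulated animals,
1,320 phenotyped in pens of 10, true components at the RFI-scale defaults)
prints:

```
REML converged in 7 iterations (restricted logL = -7200.33)

component           true    estimate        SE
var_Ad           11577.7      7692.6    2119.9
cov_DS             742.6       161.7     283.3
var_As              97.2         3.4      71.6
var_litter        1300.0      1920.9     741.1
var_group         1300.0      2083.1     876.5
var_e            11815.5     13218.4    1214.7

h^2   = 0.309   (direct additive share of phenotypic variance)
T^2   = 0.249   (total heritable share incl. social effects)
r_ADS = 1.000 (direct-social genetic correlation)
```

The direct variance lands within ~2 SE of its true value; the social
variance and covariance — carried by between-pen covariances of only 132
pens — are estimated with standard errors as large as the parameters
themselves, so a single herd can (as here) put them near a boundary.  That
sampling behaviour is exactly why the test suite validates the estimator
over many replicate herds rather than one draw, and why the field leans on
the replicate-mean experiments this package ships.  `examples/` contains
one short script per capability (trait
formulas, REML fit, genotype QC, genome scans, full pipeline); the
command-line entry point `sociogwas` exposes the same steps as subcommands
(`simulate`, `traits`, `fit`, `qc`, `scan`, `annotate`, `run`).

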