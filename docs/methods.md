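# Methods

## The model

For group-housed animals, the phenotype of animal *i* in a pen of size *n*
is decomposed into a direct and a social part:

    P_i = A_D,i + Σ_{j∈pen(i), j≠i} A_S,j + E_i ,

where `A_D` is the animal's direct breeding value (its genetic effect on its
own phenotype) and `A_S` its social breeding value (its genetic effect on
each pen-mate's phenotype).  Stacked over records this is the mixed model

    Y = X b + Z_D a_D + Z_S a_S + W l + V g + e ,

with fixed effects **b** (sex, tested year-month), random litter effects
**l** ~ N(0, σ²_litter I), random pen ("group") effects **g** ~ N(0,
σ²_group I) and residual **e** ~ N(0, σ²_e I).  Row *i* of `Z_S` is 1 at the
columns of *i*'s pen-mates and 0 elsewhere — an animal's own social value
never enters its own record.  The genetic effects are jointly distributed

    var([a_D; a_S]) = G0 ⊗ A,   G0 = [[σ²_Ad, σ_Ads], [σ_Ads, σ²_As]] ,

with `A` the pedigree numerator relationship matrix (tabular recursion;
non-phenotyped ancestors are carried so their records tie relatives
together).

### REML

The covariance of the records is a linear combination of six fixed
structure matrices (`A_rec`, `S A_rec + A_rec Sᵀ`, `S A_rec Sᵀ`, `W Wᵀ`,
`V Vᵀ`, `I`, where `S` is the pen-mate indicator among records), so the
restricted likelihood is evaluated in closed form per candidate component
vector.  Components are estimated by average-information (AI) REML:

* AI steps with step-halving and a Levenberg–Marquardt ladder (the AI
  matrix regularised toward scaled gradient ascent when near-singular), so
  every accepted step strictly increases the restricted log-likelihood; the
  per-iteration history is monotone by construction.
* Feasibility: `G0` is projected to the PSD cone by eigenvalue clipping at
  1e-8 × trace; plain variances are floored at ~1e-10 of the phenotypic
  variance (σ²_e at 1e-8) so the covariance stays invertible.
* Boundary treatment 1 (collapsing variance): a component held at its floor
  with an outward gradient for two consecutive iterations is pinned there
  and removed from the step; pinning σ²_As (or σ²_Ad) also pins σ_Ads at 0.
  A pinned component is released (at most twice per fit) if its gradient
  turns inward at the reduced optimum.
* Boundary treatment 2 (correlation edge): when the genetic correlation
  pins at ±1, plain projected steps crawl along the cone; the fitter then
  optimises *on* the edge via cov = s·√(σ²_Ad σ²_As) (chain-rule reduction
  of gradient and AI matrix), releasing the constraint when the covariance
  gradient points into the interior.
* Convergence when |Δ logL| < 1e-8, when no feasible ascent step exists
  (a stationary/boundary optimum), or when 25 consecutive iterations gain
  less than 0.05 log-units in total (a nearly unidentified direction, where
  each O(n³) iteration buys nothing of statistical consequence); 200
  iterations maximum.  The ladder rung that produced the last accepted step
  is re-tried right after the raw AI step, so boundary-hugging fits do not
  pay the full ladder every iteration.  Fits that still stall get a bounded
  Nelder–Mead polish of the projected restricted likelihood, and datasets
  of ≤300 records are always polished (their evaluations are cheap and
  their boundary optima are the awkward ones).  Non-convergence is reported
  in `VarianceComponents.converged`, never silently.
* Standard errors: square roots of the diagonal of the inverse AI matrix at
  the optimum.
* Starting values: 50% of the OLS residual variance to σ²_e, the remainder
  split 80/5/0/7.5/7.5 over σ²_Ad/σ²_As/σ_Ads/litter/group.

BLUPs of all random effects follow from the fitted components
(`â = Ĉov(u, y) P y`), and the identity Y = Xb̂ + Z_D â_D + Z_S â_S + Wl̂ +
Vĝ + ê holds exactly (asserted in tests).

### Derived summaries

* σ²_P = σ²_Ad + σ²_litter + σ²_group + σ²_e — the single-animal
  ("classical") phenotypic variance; h² = σ²_Ad/σ²_P.
* σ²_TBV = σ²_Ad + 2(n−1)σ_Ads + (n−1)²σ²_As — the variance of total
  breeding values A_D + (n−1)A_S.
* σ²_TP = σ²_P + (n−1)·[2σ_Ads·Ā + (n−2)σ²_As·Ā + σ²_group] with Ā the mean
  pen-mate relationship (0 for unrelated mates); T² = σ²_TBV/σ²_TP.  The
  σ²_P/σ²_TP compositions are this package's documented conventions (the
  quantities are standard, their exact composition is often left implicit
  in the literature).
* r_ADS = σ_Ads/√(σ²_Ad·σ²_As), defined as 0 when either variance is 0.

### Pseudo-phenotypes

Genome scans use per-animal responses that keep exactly one genetic term
plus the residual: `dge_i = â_D(i) + ê_i` and `sge_i = (Z_S â_S)_i + ê_i`
(everything else — fixed effects, the other genetic term, litter, group —
removed).  Animals without genotypes simply don't enter the scan stage;
their records still sharpen the REML/BLUP stage.

## Genome scans

**Single-locus.**  Univariate LMM `y = μ + x m + a + e` with
`a ~ N(0, σ²_g K)`; K is the VanRaden centred GRM from the QC-passed
dosages (pedigree-A available as an alternative).  The null variance ratio
δ = σ²_e/σ²_g is REML-estimated once through the eigendecomposition of K
(grid bracketing of log₁₀ δ on [−6, 6] plus bounded refinement) and reused
for every SNP — the standard approximation; exact per-SNP re-estimation is
available behind a flag.  Each SNP gets a 1-df Wald chi-square; with K = I
the whole machinery provably reduces to ordinary least squares (asserted
against `scipy.stats.linregress`).  Tiers use strict inequalities:
p < 5×10⁻⁸ genome-wide, p < 5×10⁻⁷ suggestive (a p equal to a threshold is
not promoted).

**Multi-locus (two stages).**  Stage 1 keeps loci with marker-test
P ≤ 0.005, capped at sample size − 2 by ascending p.  Stage 2 re-estimates
the candidates jointly under independent per-effect shrinkage priors whose
hyper-parameters maximise the marginal likelihood (automatic relevance
determination).  Each surviving effect is scored with the random-effect
likelihood-ratio LOD, LOD = (T²−1−ln T²)/(2 ln 10) with T the shrunken
effect over its joint-design standard error; retention needs LOD ≥ 3.  The
−1−ln T² term is what keeps the extremes of a pure-noise screen (marginal
t² ≈ 8–15 by selection alone) from being promoted.  Final effects of the
retained set are re-estimated by joint least squares so the reported QTN
effect and pve = 2p(1−p)β̂²/Var(y)·100 are not biased downward by the
prior.  This two-stage screen-then-shrink design represents the multi-locus
GWAS family generically; no published tool's iterative machinery is
re-implemented, and bit-compatibility with any of them is a non-goal.

## Genotype QC

Rules in fixed order: contig whitelist (autosomes "1"–"18"; sex chromosomes
and scaffolds out) → depth masking (genotypes with DP ≤ 6 become missing) →
missingness < 0.1 → MAF ≥ 0.1 (inclusive boundary by default, because
reported SNP tables in this literature include MAF = 0.100; configurable) →
exact Hardy-Weinberg test p ≥ 10⁻⁶.  Depth must precede missingness/MAF for
those to be well defined; on complete data the surviving set is
order-independent and the filter is idempotent (both asserted).  The HWE
test is the exact conditional two-sided test on the heterozygote count,
computed in log-space; its unit tests compare against a direct
binomial-coefficient enumeration.

## Trait formulas

Six traits from performance-test records: ADG = (BW₂−BW₁)/days;
FCR = ADFI/ADG; D100 = days − (weight−100)/CF with CF =
(weight/days)×1.826040 (males) or ×1.714645 (females); B100 = BFT×CF with
CF = 12.402/(12.402+0.106530(weight−100)) (males),
13.706/(13.706+0.119624(weight−100)) (females); AMW =
(BW₂^1.6−BW₁^1.6)/(1.6(BW₂−BW₁)), the exact mean of BW^0.6 along a linear
trajectory; RFI = ADFI − 1.41·ADG − 2.83·BFT − 110.9·AMW.  The correction
constants and RFI coefficients are fixed industry values and are not
re-estimated.  Body weight is kg, backfat mm; the ADG/ADFI unit (g/day vs
kg/day) is declared once per dataset and never converted silently.  RFI is
reported on the g/day scale: that is the scale on which the printed
coefficients weight backfat (mm) and metabolic weight (kg^0.6) against
feed and gain, and the scale on which this trait's phenotypic variance
(tens of thousands, SD ~160) is meaningful; kg/day inputs are converted by
an explicit factor of 1000.  Missing backfat or feed excludes an animal
from RFI/FCR only.

## The synthetic herd

The generator emulates a performance-tested pig herd with the statistical
structure the model assumes, not a particular real population:

* Pedigree: founder generation (default 200; both sexes guaranteed), then
  3 generations of random sire×dam matings with litter sizes uniform on
  8–12.  Non-founders are housed in pens of exactly 10 within their
  generation; leftovers from pen filling stay unpenned and unphenotyped.
  Pedigree depth and litter-size range are configuration, not constants.
* Breeding values: founders drawn from N(0, G0); offspring = parent average
  + Mendelian deviation with variance G0·½(1−(F_s+F_d)/2), so cov(a) =
  G0 ⊗ A holds exactly (checked against the full-sib expectation and
  founder moments).
* Phenotypes: fixed sex and year-month level effects (year-month assigned
  per pen, as test cohorts are), plus the direct+social genetic terms,
  litter, pen and residual draws.  Default variance components are the
  RFI-scale magnitudes (σ²_Ad = 11 577.72, σ²_As = 97.23, σ_Ads = 742.62,
  i.e. r_ADS = 0.70; litter and pen each 1 300 ≈ 5% of σ²_P; residual
  makes σ²_P = 25 993.18).  Fixed-effect level SDs default to 25% of
  √(σ²_Ad+σ²_e).
* Genotypes: 4 complete pens (40 animals) at independent loci (no LD),
  allele frequencies uniform on a configured range, genotypes drawn at
  Hardy-Weinberg within the genotyped sample.  Planted flaws (each locus at
  most one): non-autosomal contigs ("X", "scaffold_*"), low-depth
  genotypes (DP ≤ 6 at ~30% of calls), ~30% missingness, low MAF, and
  fully homozygous Hardy-Weinberg violators planted at intermediate
  frequency so the heterozygote deficit is decisive in 40 animals.  Causal
  loci add dosage×effect into the genotyped animals' direct/social values
  before phenotypes are drawn.
* The six-trait demo simulates three latent record-level quantities (ADG,
  ADFI, test backfat) under the social decomposition and derives raw test
  records from a 65 -> 110 kg feeding trial (per-animal test length =
  45 kg / ADG), so ADG, ADFI carry the structure directly and
  D100/B100/FCR/RFI inherit it as functions of the records (D100 in
  particular is a monotone transform of ADG under this protocol).

What the generator does **not** emulate: linkage disequilibrium (optional
block mode aside), selection or assortative mating, genotype-pedigree
consistency for the genotyped subset (their dosages are population draws,
not gene-dropped along the pedigree), body-weight homogenisation within
pens, and repeated measurements within the test period.  Passing tests
therefore demonstrate statistical correctness of the estimators under the
model's own assumptions — not robustness to real-data violations of them.

## Problem sizes and numerical choices

* Parameter-recovery experiments: 50 replicates of 2 000 animals in pens of
  10 (1 800 phenotyped); one pedigree shared across replicates with the
  covariance structure matrices precomputed once.
* A-matrix validation: 50-animal pedigree vs 10⁶ gene drops (Monte-Carlo SE
  per entry ≲ 5×10⁻⁴; tolerance 5×10⁻³).
* REML optimum validation: 6-animal dataset vs a 9-point-per-axis grid
  refined 14 times (PSD-constrained), agreement to 10⁻⁴ log-units.
* Scan calibration: 10 000 independent null SNPs, n = 200 (single-locus)
  and n = 500 (stage-1 screen).
* The demo pipeline runs 260 animals / 400 SNPs; the acceptance script
  fits five replicate herds of 1 500 animals and reports replicate means.
* Ties and degenerate inputs: monomorphic loci are never scanned (noted,
  p = NaN) and never enter the GRM; duplicate/collinear stage-2 candidates
  (|r| > 0.999) keep the smaller-p member; regionization orders SNPs by
  (statistic, contig, position) so its output is independent of input
  order; region bounds are top ± 20 kb rounded to the *nearest* 0.01 Mb,
  the convention that reproduces this literature's printed ranges; the
  candidate-gene window is closed, so a gene ending exactly 20 kb from the
  top SNP is still reported.

## Known limitations

* The social variance is weakly identified under uniformly random pen
  composition: at 2,000 animals its per-replicate sampling SD is of the
  same order as the parameter itself, and because the estimator is
  constrained (variances ≥ 0, genetic block PSD) the *mean* of replicate
  estimates of σ²_As is inflated even though the REML score is unbiased at
  the true components — the recovery experiments in the test suite measure
  exactly this.  Designs that compose pens from a small number of families
  identify σ²_As far more sharply.
* Single-trait analyses only; no bivariate REML across traits, no
  dominance, no single-step (pedigree+genomic blended) relationship.
* The scan stage inherits the small-sample caveats of a 40-animal cohort;
  no degrees-of-freedom correction is applied to the Wald chi-square (its
  calibration experiments run at larger n).
* Dense A only — pedigrees beyond ~5 000 animals would want Henderson's
  sparse A⁻¹ machinery, which is out of scope.
* The REML standard errors are asymptotic (inverse average information);
  for components near boundaries they are optimistic.
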