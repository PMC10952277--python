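# Methods

`ovistep` implements a complete desk-scale single-step genomic evaluation
pipeline for meat-sheep breeding data: genotype quality control and
parentage verification, pedigree and genomic relationship matrices,
REML variance components, pedigree-BLUP and single-step-BLUP breeding
values, and reliability/accuracy comparison — together with a synthetic
flock simulator that provides ground truth for every stage.

## The evaluation model

All analyses use one linear mixed model per trait,

    y = Xb + Za + (Z_m m) + (W p) + e,

where `y` are phenotypes, `b` fixed effects (contemporary groups, litter
size born, dam age, dam breed, embryo-transfer/foster codes, scorer,
vaccination; age at scan as a linear covariate for ultrasound traits),
`a ~ N(0, K sigma2_a)` the direct additive genetic effects, `m` an optional
maternal genetic effect (dam-linked, same relationship structure, no
direct-maternal covariance), `p` an optional permanent-environment effect
and `e ~ N(0, I sigma2_e)` residuals.  For the lamb traits with a maternal
effect (birth weight, eight-week weight) the permanent environment attaches
to the dam (shared by litters across parities); for repeated adult health
records (CMT) it attaches to the ewe herself.  Hoof and udder health scores
(four hooves / two udder halves, each 0–4) are analysed as
`ln(1 + sum of site scores)`.

Contemporary groups are flock x birth-season x sex for production traits
and month-year (with farm-year) for CMT.  Fixed effects use intercept +
drop-first dummy coding; jointly collinear columns (e.g. a covariate
constant within contemporary groups, which small simulated data sets
produce readily) are removed by pivoted QR before assembly, so the
coefficient matrix is full rank and solutions are unique under the
first-level-zero convention.  EBV contrasts are invariant to this choice.

The relationship structure `K` is the pedigree numerator matrix `A` for
conventional BLUP.  For single-step BLUP, `K = H` where

    H^-1 = A^-1 + [0 0; 0 G_b^-1 - A22^-1]

on the genotyped block: `G` is VanRaden method-1,
`G = ZZ' / (2 Σ p_j (1 - p_j))` with `Z` the 2p-centred genotype matrix and
`p_j` observed allele frequencies; `A22` is the pedigree relationship among
genotyped animals (tabular method on the ancestor-restricted pedigree).

Two adjustments make the genotyped block compatible with the pedigree
base, and both are on by default in `run_evaluation`:

* **Tuning**: an affine rescale `a + bG` matches G's mean diagonal and
  mean off-diagonal to A22's.  Observed-frequency centring places G on the
  current-population base while A22 is on the founder base; without the
  adjustment the base shift masquerades as information loss and genotyped
  animals can spuriously lose reliability relative to pedigree BLUP.
* **Blending**: `G_b = 0.95 G + 0.05 A22` guarantees invertibility (G is
  singular whenever animals outnumber informative SNPs or duplicates are
  present).

## Pedigree computations

Inbreeding coefficients come from a single-pass ancestor-traversal
(Meuwissen–Luo style): for each animal the additive relationship of its
parents is accumulated over weighted ancestor paths, giving
`F = 0.5 a(s, d)` in one forward sweep.  `A^-1` is assembled by Henderson's
rules with Mendelian-sampling variances `d_i = 0.5 - 0.25 (F_s + F_d)`
(0.75 - 0.25 F_p with one known parent, 1 with none; unknown parents are
base-population animals, no genetic groups).  The dense tabular method is
retained as the independent oracle — `A^-1 A = I` and `diag(A) = 1 + F`
are exercised on randomly generated pedigrees in the test suite.

## Genotype QC and parentage

Thresholds follow UK national genomic evaluation practice: sample call rate
>= 89.4%, SNP call rate >= 89.4%, MAF >= 0.05, and Hardy–Weinberg
equilibrium at p >= 0.05 by a one-degree-of-freedom chi-square
goodness-of-fit against p², 2pq, q² (no continuity correction), computed
after the sample filter.  Parentage uses opposing homozygotes on the SNPs
shared across arrays: a genotyped recorded parent is confirmed when the
conflict rate is <= 1%; otherwise every genotyped candidate of the correct
sex born earlier is scanned and the unique best candidate at or below the
threshold is assigned, else the slot is set to unknown.  Duplicate samples
must be concordant on shared non-missing calls and are resolved by array
priority 50K > HD > LDv2 > LDv1 (call rate breaking ties).  The conflict
denominator excludes loci missing in either sample and a warning is raised
below 100 informative loci.

## REML

Univariate variance components are estimated by EM-REML with
average-information acceleration: five EM warm-up iterations (each with a
guaranteed increase of the restricted likelihood, which the tests assert
iteration by iteration), then damped AI/Newton steps that fall back to EM
whenever a step would leave the parameter space or decrease the
likelihood.  The restricted likelihood is evaluated through the
mixed-model-equations identity
`log|V| + log|X'V^-1X| = log|M| + n log sigma2_e + Σ_r (q_r log sigma2_r + log|K_r|)`,
verified against a dense-V computation during development and in the test
suite's oracle comparisons.  Traces of `K^-1 C` blocks come from sparse-LU
solves of the MME for the random-effect columns.  Components are floored
at `1e-8 sigma2_p` (flagged via `boundary`), convergence is a relative
parameter change below 1e-6 (default), and standard errors come from the
inverse AI matrix (h² by the delta method).

Bivariate analyses fit a 2x2 direct-genetic and a 2x2 residual covariance
by EM on animals recorded for both traits; other random effects are not
crossed between traits.  EM keeps both covariance matrices positive
semi-definite; when a genetic variance collapses to its floor the
correlation is reported non-estimable with reason "negative sum of
squares", the situation sequential REML software reports on such pairs.
Genetic correlations from shallow pedigrees at a few hundred animals carry
standard errors of 0.1–0.3, so recovery tests use three-generation
pedigrees and replicate means with matching tolerances.

## Reliability and accuracy

Exact reliabilities are `1 - PEV_i / (k_ii sigma2_a)` with `PEV` from the
inverse of the MME coefficient matrix and `k_ii` the diagonal of the
relationship structure actually fitted (1 + F under A, the blended genomic
diagonal for genotyped animals under H).  This is feasible at desk scale
(default guard: 20,000 equations) and serves as the gold standard.

The scalable approximation follows the two-step pattern of production
systems: (1) per-animal record information after absorbing the fixed
effects — `m_i = n_i - s_i'(X'X)^-1 s_i`, which reduces to the classic
contemporary-group absorption `n_i (1 - n_i/N)` when only CGs are fitted —
plus, in single-step mode, a genomic term from the genotyped-block
correction `Delta = G_b^-1 - A22^-1`: its diagonal net of absorbing the
other genotyped animals' equations through the Delta couplings, so genomic
precision is discounted by how well the connected reference animals are
themselves estimated; (2) propagation of information between parents and
offspring by two-pass absorption of the animal block over the pedigree
graph (progeny absorbed upward with Mendelian-variance weights, then both
parents absorbed jointly as a 2x2 block), iterated to a 1e-6 fixed point.
Mate couplings beyond the sire-dam pair and inbreeding are neglected at
this level.  On ~300–500-animal fixtures the approximation tracks the
exact values with correlation >= 0.95 and mean absolute deviation <= 0.025
in both modes; accuracy is the square root of reliability everywhere.

Known limitation: when a contemporary group coincides with a single sire
family (very few sires per flock-year-sex group) the diagonal absorption
overstates information by up to ~0.06 reliability; the approximation is
intended for populations where groups span several families.

## The synthetic flock

The simulator generates the study conditions end to end:

* **Pedigree**: founders split over `n_flocks` flocks, hierarchical
  matings (each sire serving `dams_per_sire` dams within flock, 15% of
  sires exchanged across flocks so contemporary groups stay genetically
  linked), litter sizes 1 + Poisson, non-overlapping generations.
* **Genotypes**: biallelic SNPs gene-dropped from founder frequencies
  drawn uniformly on (0.05, 0.5]; founders at Hardy–Weinberg, offspring
  receive one Mendelian-sampled allele per parent.  Genotyping error
  (single-allele flips), missing calls and an ungenotyped mask (biased
  toward older animals) are applied afterwards; array labels (HD / 50K /
  LDv1 / LDv2) are attached per sample.
* **Traits**: by default the direct genetic values are sums of normalized
  SNP effects over the gene-dropped genome ("marker" architecture), which
  satisfies the additive recursion
  `a = 0.5(a_s + a_d) + Mendelian deviation` while making the genomic
  relationship genuinely informative about the trait — the mechanism
  single-step evaluation exploits.  A "polygenic" switch reverts to the
  pure pedigree recursion (markers then carry no trait signal, and
  single-step cannot beat pedigree BLUP by construction).  Maternal values
  use the pedigree recursion with independent draws; dam permanent
  environment is i.i.d. normal.  Fixed-effect level values are drawn once
  per level from `N(0, fixed_effect_sd^2)`.  Phenotypes are withheld for a
  configured fraction of animals, preferentially in the youngest
  generation — the selection-candidate stratum of interest.
* **Health scores**: a latent value per ewe-visit on the ln(sum+1) scale
  is mapped to per-site 0–4 scores by greedy decomposition of
  `round(exp(latent) - 1)`, keeping the transform exactly invertible;
  ewes are scored 1–5 times.
* **Planted errors**: `corrupt_pedigree` swaps recorded parents of a
  random fraction of genotyped animals to same-sex non-parents (genotyped
  where possible) and returns the plant list for recall scoring.

Everything is deterministic given the configuration seed (one seed stream
per operation).  What the simulator does **not** model: linkage
disequilibrium and chromosome structure, selection across generations,
genotype-by-environment interaction, overlapping generations, and real
call-rate heterogeneity between arrays.  Passing tests therefore
demonstrate internal correctness of the estimators and the direction and
structure of single-step gains — not the magnitudes to be expected on any
particular commercial data set.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen so every stage has an
independent oracle: random pedigrees up to 300 animals against the tabular
method; ~450-animal flocks for evaluation properties; ~300–500-animal
fixtures for reliability-approximation agreement; heritability-recovery
replicates at ~3,000 phenotyped animals; accuracy-comparison replicates on
~1,200-animal flocks with 600-SNP panels, 40% genotyped.  At these sizes
the full acceptance computation completes in minutes on one core.
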