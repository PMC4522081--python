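# Methods

`hapblock` implements genomic prediction with linkage-disequilibrium (LD)
haplotype blocks ("haploblocks") as predictor variables, together with the
machinery needed to exercise the method end to end on simulated pedigreed
populations: marker editing, block construction, Bayesian mixed-model
samplers, QTL-haploblock selection and forward-validation statistics.

## Prediction models

Both models share the linear mixed model

```
y = 1 mu + M g + Z a + e,        e ~ N(0, D sigma_e^2)
```

* `y` — deregressed proofs (DRP) of the training animals. A DRP is a
  pseudo-phenotype derived from an estimated breeding value, carrying its
  own reliability `r2_i`.
* `M` — design matrix. For the individual-SNP model a column per marker with
  allele dosages {0,1,2}; for the haploblock models a column per
  (block, variant) with variant dosages {0,1,2} (see below).
* `a` — residual polygenic effect, `a ~ N(0, A sigma_a^2)` with `A` the
  pedigree numerator relationship matrix. All animals (training and
  candidates) are carried in `a`; `Z` links phenotyped animals only.
* `D = diag(1/w_i)` with `w_i = r2_i / (1 - r2_i)`: records with higher
  reliability get smaller residual variance. Reliabilities are clamped to
  [0.01, 0.99] before weighting so every `w_i` is positive and finite (the
  weighting formula itself has no cap).

**Bayesian BLUP** places a single common variance on all effects,
`g ~ N(0, I sigma_g^2)` — a ridge-type shrinkage model.

**Four-component Bayesian mixture** draws each effect from one of four
normal components with fixed mixing proportions
`pi = (0.889, 0.1, 0.01, 0.001)` and component variances estimated under
the ordering constraint `s1 < s2 < s3 < s4`. The first class is a free
small variance, not a point mass at zero: the mixture is a four-normal
model throughout. All location and variance parameters carry improper
uniform priors.

### Gibbs sampler

A single-chain Gibbs sampler updates, per cycle: the mean (weighted
normal); each effect `g_j` by single-site weighted normal — for the mixture
the component label is drawn first from the `pi`-weighted marginal
likelihood of the four components with `g_j` integrated out; each polygenic
value `a_i` by single-site normal using the sparse `A^-1`; and the
variances from their flat-prior conditionals, scaled inverse chi-square
with `nu = count - 2` (floored at 1) and scale equal to the relevant sum of
squares. This `nu` convention is the standard conditional under an improper
uniform prior on a variance; other conventions exist, and the exact choice
only matters at very small effect counts.

The ordering constraint on the mixture variances is enforced by joint
proposal: the four variances are drawn from their conditionals and the
draw is accepted only if strictly ordered, with up to 10 retries, after
which the draw is projected by sorting. Empty components keep their current
value (their conditional is improper). Posterior means are accumulated
after burn-in with optional thinning; GEBV are
`GEBV_i = sum_j m_ij g_hat_j + a_hat_i` from the stored posterior means,
with candidate animals' polygenic values taken from the chain (they are
carried without a phenotype link).

Default chains are 5000 cycles with 2000 burn-in — sized to the desk-scale
data simulated here; production-scale analyses of this kind conventionally
use 50 000 / 20 000, available by configuration. Convergence can be
monitored through the optional variance traces
(`ModelSpec(collect_traces=True)`) or by correlating GEBV from two chains
with different seeds. All randomness flows from one seeded generator and
the compiled update loops are deterministic, so a seed reproduces a chain
bit for bit.

### Numerical choices

* Variance draws are floored at 1e-12; a non-finite residual aborts with
  the cycle number.
* Initial values: `mu` = weighted mean of `y`, effects zero,
  `sigma_g^2 = var(y)/(2q)`, mixture variances at (0.1, 1, 10, 100) times
  that, `sigma_a^2 = var(y)/4`, `sigma_e^2 = var(y)/2`. With flat priors
  the chain forgets these quickly; they only set the pre-burn-in scale.
* Effect ranking ties are broken by genome order (chromosome, position),
  making the ranking deterministic.

## Haploblocks

Pairwise LD between biallelic markers is computed from phased haplotype
counts: `D = pAB - pA pB`, `D' = D / Dmax` (with `Dmax` the largest |D|
attainable at the observed allele frequencies and the sign of D; `D' = 0`
when `D = 0`), `r2 = D^2 / (pA(1-pA) pB(1-pB))`.

A haploblock is a run of adjacent markers on one chromosome in which
*every* pair satisfies `|D'| >= 0.45` (configurable). The defining
criterion is all-pairs; the partitioning algorithm is a deterministic
greedy left-to-right scan: start a block at the first unassigned marker and
extend it while the next marker clears the threshold against every current
member. Every marker lands in exactly one block; single-marker blocks are
allowed. Raising the threshold can only shorten blocks.

Each block is treated as a multi-allelic locus. Its allele catalogue is the
set of distinct haplotype strings observed over the block's span in the
*training* haplotypes, ordered by descending frequency (ties
lexicographic). Blocks with exactly one catalogued variant carry no
contrast and are excluded from the design. The design matrix has one
column per (block, variant); a sample's two haplotypes are matched against
the catalogue, so reference samples' dosages sum to 2 per block, while a
test haplotype absent from the catalogue contributes nothing (novel
variants have no estimated effect; no "other" bucket is created). LD,
blocks and catalogues are computed on training haplotypes only, and test
animals are encoded against the training catalogue — the test set never
influences the predictors.

## QTL-haploblock selection

The absolute posterior-mean SNP effects from an all-SNP fit are ranked;
the non-excluded blocks containing at least one of the top-`k` markers
form the QTL-haploblock set (deduplicated, genome order). When several top
markers share a block, `k` is not topped up, and top markers whose block is
excluded are skipped. The selection model always matches the prediction
model: BLUP-ranked blocks are fit with BLUP, mixture-ranked with the
mixture. The baseline selects blocks containing `k` uniformly sampled
markers, repeated over replicates.

At the simulated scale (3000 markers) the default `k` grid is
{50, 100, 250, 500, 1000, 2000}, proportional to the grids used on
real high-density data (thousands to tens of thousands of markers out of
hundreds of thousands).

## Pedigree relationship matrix

`A` is built by the tabular recursion (`A_ij = (A_is + A_id)/2`,
`A_jj = 1 + A_sd/2`) on a topologically sorted pedigree; inbreeding is
exact, not assumed zero, because multi-generation random mating produces
inbred matings. `A^-1` is assembled directly by Henderson's rules with
Mendelian-sampling variances `D_i = 0.5 - 0.25 (F_s + F_d)` (unknown
parents enter with `F = -1`), with `F` computed by tracing the Cholesky
rows of `A` through the ancestors — an independent route from the tabular
`A`, which the tests exploit (`A A^-1 = I` to 1e-8). Matrices are dense;
the implementation targets desk-scale pedigrees (up to a few thousand
animals).

## Evaluation

Forward validation: the last simulated generation is the test set (a
birth-date proxy). For a GEBV vector against test DRP:

* reliability `r^2 = Cor^2(DRP, GEBV) / mean(r2_DRP)` — the squared Pearson
  correlation corrected by the mean DRP reliability of the test animals
  (an aggregate correction, not per-animal);
* bias `b - 1`, with `b` the least-squares slope of DRP on GEBV.

Two models on the same test set give dependent correlations with DRP;
equality is tested by the Hotelling-Williams t-statistic

```
T = (r_di - r_dj) sqrt((n-3)(1+r_ij) / (2|R|))
    / sqrt(1 + (n-3)(r_di+r_dj)^2 (1-r_ij)^3 / (8(n-1)|R|))
```

with `|R|` the determinant of the 3x3 correlation matrix of
(DRP, GEBV_i, GEBV_j); under the null `T ~ t_{n-3}`, two-tailed p-values.
Pearson correlation is used throughout.

## Synthetic populations

The generator emulates the data structure of a progeny-tested dairy
population at desk scale:

* **Founder LD.** Founder haplotypes copy segments from a small ancestral
  pool (default 8 haplotypes), switching pool members with probability
  0.06 per marker. Long shared segments give strong local |D'|; with the
  defaults roughly three quarters of markers fall in multi-SNP blocks at
  the 0.45 threshold. A bounded-retry guard redraws pool columns until all
  founder MAF >= 0.01.
* **Pedigree.** Discrete generations of random monogamous mating
  (shuffle, pair, two offspring per pair keeps the generation size
  constant), Haldane recombination (Poisson crossover counts, uniform
  positions, no interference), 1 Morgan per chromosome. Defaults: 200
  founders, 4 generations, 1000 animals, so the forward split is 800
  training / 200 test.
* **Trait.** 40 QTL at uniform positions; effects from the same
  four-class mixture as the prediction model (relative variances
  1e-5…1e-2), rescaled so the realized TBV variance corresponds to
  h2 = 0.3 against a unit total. DRP are `TBV_i + e_i` with per-animal
  reliability uniform in (0.6, 0.95) and
  `Var(e_i) = Var(TBV)(1 - r2_i)/r2_i`, so the squared DRP–TBV correlation
  matches the reliability. DRP are simulated directly on the TBV scale;
  deregression of estimated breeding values from a national evaluation is
  deliberately outside this package — the models only need (value,
  reliability) pairs with this error structure.

What the generator does **not** emulate: coalescent-exact LD decay,
selection or assortative mating, overlapping generations, genotyping
error, sex chromosomes, or the shrinkage/parent-average artefacts of real
deregressed proofs. Passing tests therefore demonstrate that the machinery
is correct and that the method's qualitative behaviour (haploblock and
QTL-haploblock predictions tracking true breeding values, selection
beating random subsets, reliability plateauing in `k`) holds under a clean
additive architecture — not that particular reliabilities will be attained
on real cattle data.

## Problem sizes used in the checks

The shipped study conditions are the desk-scale defaults above: 3 x 1000
markers, 1000 animals, 5000-cycle chains, mid-grid `k = 500`, 10
random-selection replicates. They are chosen so the whole experimental
design — simulation, all-SNP fits, block construction, selection grid,
haploblock fits, evaluation — runs end to end on a single CPU in minutes
while leaving every stage's statistical behaviour measurable.

## Known limitations

* Dense `A`/`A^-1` limits pedigrees to a few thousand animals.
* Single-site Gibbs mixes slowly for very dense LD; the two-chain GEBV
  correlation diagnostic is the intended check.
* The variance conditionals' `nu = count - 2` floor matters for nearly
  empty mixture classes, where the class variance is weakly identified.
* VCF input must be fully phased and complete; phasing and imputation are
  upstream concerns.
* `r2`-based blocking is available through the same machinery only in the
  sense of pre-pruned complete-LD chains; the block criterion itself is
  |D'|.
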