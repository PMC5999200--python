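# Methods

This note documents the statistical machinery, the defaults and why
they are what they are, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Mixture model

The conditional (empirical-Bayes) GSI formulation.  For collection `c`,
locus `l` with `A_l` observed alleles, baseline counts `x[c,l,a]` over
`n[c,l]` gene copies:

    theta[c,l,a] = (x[c,l,a] + lambda_l) / (n[c,l] + A_l * lambda_l)

with per-allele prior mass `lambda_l = 1/A_l` (unit total mass per
locus).  The allele index is always built on baseline ∪ mixture, so a
mixture-private allele has positive frequency in every collection and
no fish gets likelihood zero.  Baseline frequencies are *held at their
posterior means* during mixture MCMC rather than resampled; this is the
conditional fit that makes small instances tractable enough to verify
against direct numerical integration (see tests), at the cost of
understating baseline-sampling uncertainty in the credible intervals.
Full-Bayes baseline resampling is deliberately out of scope.

Likelihoods are diploid Hardy–Weinberg products over typed loci;
missing loci contribute a constant and therefore cancel.  The Gibbs
sweep alternates latent origins `z_i | pi` (categorical, weights
`pi_c * L_ic`) and `pi | z` (Dirichlet).  Per-fish posteriors are
Rao-Blackwellized (the within-sweep origin probabilities averaged over
retained iterations), which converges faster than averaging indicator
draws.

**Priors on pi.**  The default is `alpha = 1` per collection (a flat
Dirichlet over the simplex).  Beware its total mass: with `C`
collections and a mixture of size `n`, a 100%-pure mixture's posterior
mean for the true unit cannot exceed `(n+1)/(n+C)` — 0.60 at `C = 35`,
`n = 50` — so with many collections and small mixtures the flat prior,
not the data, bounds the estimate.  The alternative `alpha = 1/C`
(total mass 1, the convention of the established GSI tools this package
parallels) is available via `McmcConfig(pi_prior="one_over_c")` and is
what the acceptance script uses for its evaluation stages.

**Defaults.** `n_iter = 20000`, `burn_in = 1000`, `n_boot = 100`
(production settings).  For the small synthetic problems in the test
suite and acceptance script, posterior means converge well before 2,000
iterations, so those runs use `n_iter` of 800–5,000 with proportionally
shorter burn-in; this is a choice of problem size, not of model.
Credible intervals are central (equal-tailed) 95% intervals of the
retained reporting-unit traces.

**Parametric bootstrap.**  `n_boot` mixtures of the original size are
simulated from the posterior-mean frequencies at the estimated
collection proportions, re-fitted with the same sampler, and the mean
re-estimation bias is subtracted at the reporting-unit level; negative
values are clamped to zero and the vector renormalized (a documented
deviation from any exact reference: the clamp is needed because the
correction can overshoot near the simplex boundary).  Bootstrap fish
are *new* draws from `theta` — no leave-one-out decrement — because
real mixture fish are not baseline members.

## Leave-one-out discipline

Self-assignment removes the focal fish's two gene copies per typed
locus from its own collection's counts before computing `theta` for
that collection (other collections are untouched).  Simulated fish in
the evaluation designs are drawn from the Pólya-urn posterior
predictive of their source collection — copy 1 from
`(x+lambda)/(n+A*lambda)`, copy 2 duplicating copy 1 with probability
`1/(n+A*lambda+1)`, else a fresh predictive draw — and their drawn
copies are *not* added to the baseline when they are subsequently
assigned.  Both conventions remove the optimism of evaluating a fish
against a baseline that contains its own gene copies.

## Summary statistics

* **Heterozygosity.**  H_O is the observed heterozygote fraction; H_E
  is Nei's unbiased estimator `(2n/(2n-1)) * (1 - sum p^2)` per
  collection × locus, averaged over collections then loci.
* **Hardy–Weinberg tests.**  Monte Carlo exact test: gene copies are
  pooled within a collection × locus cell and re-paired at random; the
  statistic is the conditional probability of the genotype
  configuration given allele counts (Guo–Thompson).  P-values use the
  **mid-p convention** (half the tie mass at the observed statistic):
  with a discrete statistic at realistic sample sizes the full-tie
  convention is visibly conservative (null p-values stochastically
  larger than uniform and a KS test against U(0,1) rejects), while
  mid-p calibrates.  Monomorphic cells and cells with fewer than two
  typed individuals are untestable and excluded from the Bonferroni
  denominator.  A permutation test was chosen over asymptotic
  chi-square because multiallelic loci have sparse genotype classes;
  the seed is a required argument of any reported run.
* **F_ST.**  Weir & Cockerham's theta, multiallelic, with variance
  components summed over alleles and loci (ratio of sums, the standard
  multi-locus estimator).  Per-allele heterozygote-carrier counts are
  tracked in the count table for this purpose.  Negative estimates are
  reported as computed; clamp only in display layers.
* **Chord distance.**  `d(i,j) = sqrt( mean_l (1 - sum_a
  sqrt(p_il_a * p_jl_a)) )` over co-typed loci — the squared-chord
  average convention under which disjoint allele sets give distance 1.
  Other normalizations (2/pi factors) exist; only the tree *topology*
  is consumed downstream, so the convention choice is cosmetic here,
  but it is stated so users can compare against other software.
* **Neighbor joining.**  Saitou–Nei via scikit-bio (ties resolved by
  its first-minimum rule).  Bootstrap support resamples *loci* with
  replacement (not individuals), recomputes the chord matrix and tree,
  and labels each internal edge with the percentage of replicates
  containing its bipartition; supports below 50% are omitted from the
  output labels as is conventional for publication trees.

## Reporting-unit formation

The lumping of collections into reporting units is, in real studies, an
iterative judgment call.  The package encodes the stated evidence
sources as a deterministic rule set so a proposal is reproducible:
(1) collections under `min_n = 30` join their nearest tree neighbor;
(2) pairs with reciprocal top-assignment confusion ≥ 0.20 in both
directions are unioned; (3) unions are transitively closed, and every
union records its triggering evidence.  The 0.20 default reliably
captures pairs that are genuinely indistinguishable on synthetic data
while leaving moderately separated pairs alone.  Geographic adjacency
is accepted only as explicit user input, never inferred.  The output is
decision support; the final map is the analyst's call.

## Panel QC

Five rejection criteria, each an explicit statistic with a threshold:
fewer than 4 distinct alleles; mean per-sample read depth < 200 or
> 10,000 (mean is the default summary; median and min are exposed
because the convention varies between labs); any individual carrying
more than two alleles (multi-copy amplification); failed/ambiguous call
fraction > 5%; and a null-allele proxy — `F_IS > 0.20` *and* one-sided
heterozygote-deficit mid-p < 0.05.  The null-allele proxy needs an
adequate test panel: with ~40 samples the F_IS sampling noise alone
falsely rejects a few percent of clean loci, while at ~80 samples false
rejects essentially vanish.  Screens on small test panels should raise
`fis_null` or treat criterion (i) flags as review items.

Duplicate-based genotyping error counts discordant allele calls between
replicate pairs as multiset differences per locus (a het/hom mismatch
sharing one allele is **one** error) divided by allele calls compared
(two per co-typed locus per pair).  Note the estimator's denominator
counts comparisons, not calls: since both replicates carry independent
errors, its expectation is ~`2e(1-e)` for a per-call error rate `e`.
The generator's default `error_rate = 0.0007` is chosen so the
*measured* duplicate-based rate emulates the ~0.14% panel-level figure
such screens typically report.

## Synthetic data

Balding–Nichols divergence: per locus, `A_l ~ 2 + Poisson(mean - 2)`
alleles, ancestral frequencies `~ Dirichlet(1)`, population frequencies
`~ Dirichlet(p_anc * (1-F)/F)`.  An optional two-level hierarchy draws
group centers at `f_between` and populations within groups at
`fst_target`.  `SimConfig.reference()` encodes the reference study
conditions: 35 rivers containing six small clusters of nearly
indistinguishable rivers (sizes 2/3/4/2/2/2 at `F_within = 0.002`)
among 20 well-separated ones (`F_between = 0.049`), chosen in closed
form so mean pairwise F_ST ≈ 0.051 (13 of 595 pairs near 0.002, the
rest near 0.051) with realized minima near 0; 101 loci at a mean of 8.4
alleles; 42 fish per river; 2% missing calls; 56 duplicates.  This is
exactly the structure that makes reporting-unit pooling necessary: the
merge rules recover most planted clusters, collapsing 35 collections to
roughly 26-28 units depending on the seed.

What the generator does **not** emulate: linkage between loci,
stutter/length-dependent allele-calling artifacts, temporal cohort
structure, uneven sample sizes, and the long upper tail of real
pairwise F_ST (realized max ≈ 0.06-0.08 versus ~0.15 in comparable real
baselines).  Its expected heterozygosity (~0.73 under Dirichlet(1)
ancestral frequencies) is higher than typical coastal panels (~0.5),
i.e. the synthetic panel is somewhat *more* informative per locus than
a real one.  Passing tests therefore demonstrate correctness of the
estimators and honest behavior of the evaluation designs — not that any
particular real baseline will achieve a given accuracy.

## Evaluation designs and scoring

* 100% simulations: per reporting unit, mixtures composed entirely of
  that unit (fish drawn from member collections with equal weight by
  default; size-proportional optional).  Two quantities are reported
  separately because they are often conflated: the *mixture-level*
  proportion credited back to the true unit, and *individual-level*
  accuracy/efficiency at the threshold.
* Equal-proportion and Dirichlet(1.5) mixtures: tidy truth-vs-estimate
  tables; the Dirichlet design is the most informative because it
  sweeps compositions across the simplex.
* Scoring at threshold `t = 0.70`: a fish is assigned to its argmax
  reporting unit iff that posterior ≥ t.  Accuracy = correct /
  assigned-to-unit; efficiency = correct / truly-belonging; retention =
  assigned / truly-belonging; additionally the overall correct fraction
  (correct / all fish) is reported — unlike threshold-precision, which
  saturates near 1 because wrong assignments rarely clear 0.70, the
  correct fraction responds to panel information content and is the
  right metric for ordering locus subsets (multiplexes).
* Units with nobody assigned report accuracy as NA, never 0.

## Numerical choices and degenerate inputs

* Likelihood rows are rescaled by their maximum before the sampler
  (per-fish constants cancel in the origin probabilities).
* Loci with zero observed alleles are dropped from frequency models
  with a warning; collections untyped at a locus fall back to the prior
  mean.
* A fish with all loci missing has equal likelihood everywhere and
  posterior equal to the (estimated) mixing proportions.
* Distance matrices are symmetrized against float noise
  (`(d + d.T)/2`) with a forced zero diagonal before NJ.
* Missingness filtering uses strict `>` (an individual missing exactly
  the threshold fraction is retained); heterozygote call order is
  normalized on read; half-called genotypes are treated as missing.
* Seeds: every stochastic routine takes an explicit seed or Generator;
  fixed seeds reproduce outputs bit-for-bit (tested end to end).

## Problem sizes in the shipped tests

The acceptance checks run at reduced scale chosen for quick iteration:
Dirichlet-recovery at 6 units × 48 loci × 20 replicates of 200 fish
(MAE of corrected estimates < 0.03); bias-correction comparison on a
two-unit skewed scenario over 50 replicates; the multiplex-subset curve
on a weakly differentiated 10-river baseline where the correct-fraction
signal (0.85 → 0.99 across 31/61/81/101 loci) dominates Monte Carlo
noise.  Production analyses should use the full defaults.
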