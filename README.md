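# gsikit

Genetic stock identification (GSI) from large multiallelic genotype
panels — built for the situation faced by managers of mixed-stock
fisheries: a **baseline** of reference collections (rivers) genotyped at
many microsatellite loci, and **mixture** samples (fishery catches) of
unknown origin whose stock composition must be estimated.

The package covers the full analysis chain:

* **Panel QC** — locus screening (null alleles, low variability,
  amplification depth, multi-copy amplification, scoring difficulty) and
  genotyping-error estimation from deliberately re-genotyped duplicate
  samples.
* **Baseline statistics** — observed/expected heterozygosity, Monte
  Carlo exact Hardy–Weinberg tests with Bonferroni correction,
  Weir–Cockerham F_ST (pairwise and per locus), Cavalli-Sforza–Edwards
  chord distance, and a neighbor-joining tree with locus-bootstrap
  support.
* **Reporting-unit formation** — a reproducible rule set that proposes
  pooling indistinguishable collections from the NJ tree, the
  leave-one-out mis-assignment matrix, and sample sizes.
* **Bayesian mixture estimation** — Gibbs-sampled mixing proportions
  with 95% credible intervals and parametric-bootstrap bias correction.
* **Evaluation by simulation** — leave-one-out self-assignment, 100%
  single-unit mixtures, equal-proportion mixtures, and
  Dirichlet-distributed "realistic" mixtures, scored as accuracy /
  efficiency / retention at a posterior threshold (default 0.70).
* **Synthetic data** — a Balding–Nichols generator (optionally
  hierarchical for regional clusters) so every stage is testable without
  external data.

## The model

Baseline allele counts `x[c,l,a]` over `n[c,l]` gene copies give each
collection `c` Dirichlet-posterior-mean frequencies

    theta[c,l,a] = (x[c,l,a] + lambda_l) / (n[c,l] + A_l * lambda_l),
    lambda_l = 1 / A_l,

so alleles unseen in a collection keep nonzero support.  A mixture
fish's likelihood under collection `c` is the diploid Hardy–Weinberg
product over its typed loci (`theta_a^2` for homozygotes,
`2 theta_a theta_b` for heterozygotes).  With a Dirichlet prior on the
mixing proportions `pi`, a Gibbs sampler alternates

    z_i | pi  ~  Categorical( pi_c * L_ic )        (latent origins)
    pi | z    ~  Dirichlet( alpha + counts(z) )    (proportions)

Reporting-unit proportions are sums of collection proportions.  The
parametric bootstrap re-simulates mixtures of the same size at the
estimate, re-fits them, and subtracts the mean re-estimation bias.
Self-assignment of baseline fish removes each fish's own gene copies
from the counts before scoring it (leave-one-out), as do the mixture
simulations, preventing optimistic accuracy.

## Worked example

`examples/05_mixture_estimation.py` builds a 6-river synthetic baseline
(48 loci, F_ST ≈ 0.05, 50 fish per river), draws a 200-fish mixture at
known proportions, and re-estimates it:

```
       truth  estimate  ci_low  ci_high  corrected
POP01   0.35     0.359   0.293    0.426      0.367
POP02   0.25     0.252   0.195    0.313      0.251
POP03   0.15     0.171   0.123    0.224      0.169
POP04   0.10     0.078   0.045    0.118      0.075
POP05   0.10     0.093   0.057    0.136      0.093
POP06   0.05     0.048   0.023    0.080      0.045

mean absolute error of corrected estimates: 0.012
```

Each row is one reporting unit: the true simulated proportion, the
posterior-mean estimate with its central 95% credible interval, and the
bootstrap-corrected value.  Every interval covers its truth and the
corrected estimates are within ~0.01 of it on average.  The other
scripts in `examples/` demonstrate baseline summaries, panel QC,
reporting-group formation, self-assignment, and the three simulation
designs the same way.

A `gsi` command-line tool wraps the same stages
(`gsi baseline-summary | propose-groups | simulate | subset-accuracy |
estimate | panel-qc | synth`); run `gsi --help`.

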