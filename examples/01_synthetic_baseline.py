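"""Generate a synthetic multi-population baseline and summarize it.

Builds a small Balding-Nichols baseline (8 rivers, 40 loci), then
computes the descriptive statistics a stock-identification study reports
first: alleles per locus, observed/expected heterozygosity, and the
distribution of pairwise F_ST.
"""

import numpy as np

from gsikit import SimConfig, generate_baseline
from gsikit.popgen_stats import allele_counts, heterozygosity, pairwise_fst

cfg = SimConfig(
    n_pops=8, n_loci=40, mean_alleles_per_locus=8.4, fst_target=0.05,
    n_per_pop=40, seed=1,
)
synth = generate_baseline(cfg)
counts = allele_counts(synth.baseline)
het = heterozygosity(counts)
fst, per_locus = pairwise_fst(counts)
upper = fst.to_numpy()[np.triu_indices(8, 1)]

print(f"baseline: {synth.baseline.genotypes.n_individuals} fish, "
      f"{counts.n_loci} loci, {counts.index.total_alleles} alleles "
      f"({counts.index.mean_alleles_per_locus} per locus)")
print(f"H_obs = {het.h_o_overall:.3f}, H_exp = {het.h_e_overall:.3f}")
print(f"pairwise F_ST: mean {np.mean(upper):.3f}, "
      f"range {np.min(upper):.3f}-{np.max(upper):.3f}")
print()
print("F_ST near the 0.05 drift target confirms the generator produced the")
print("intended level of differentiation; heterozygosity reflects the")
print("allele-frequency skew of the simulated ancestral pool.")
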