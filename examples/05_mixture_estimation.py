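"""Estimate the stock composition of a mixed fishery sample.

A mixture of 200 unlabeled fish is drawn from known proportions, then
re-estimated with the Gibbs sampler: posterior means, 95% credible
intervals, and parametric-bootstrap bias-corrected proportions.
"""

import numpy as np
import pandas as pd

from gsikit import McmcConfig, SimConfig, fit_mixture, generate_baseline, generate_mixture

synth = generate_baseline(
    SimConfig(n_pops=6, n_loci=48, fst_target=0.05, n_per_pop=50,
              n_duplicates=0, seed=7)
)
truth = np.array([0.35, 0.25, 0.15, 0.10, 0.10, 0.05])
mixture, origins = generate_mixture(synth.true_freqs, truth, 200, seed=8)

cfg = McmcConfig(n_iter=5000, burn_in=500, n_boot=50, seed=9)
res = fit_mixture(mixture, synth.baseline, cfg)

out = pd.DataFrame({
    "truth": truth,
    "estimate": res.ru_pi_hat.round(3),
    "ci_low": res.ci["low"].round(3),
    "ci_high": res.ci["high"].round(3),
    "corrected": res.pi_corrected.round(3),
})
print(out.to_string())
mae = float(np.abs(res.pi_corrected.to_numpy() - truth).mean())
print(f"\nmean absolute error of corrected estimates: {mae:.3f}")
print("Each credible interval should cover its true proportion ~95% of the")
print("time; the bootstrap correction removes the systematic part of the")
print("re-estimation error measured on mixtures resimulated at the estimate.")
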