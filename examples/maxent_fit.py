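"""Maximum-entropy fitting and correlated- vs independent-hinge testing.

Generates a synthetic α-angle histogram from strongly correlated hinge
weights (mass only on pairs combining a strongly bent and an unbent
hinge), then fits both weight models under the reduced-χ² = 1 constraint.
The general model reaches χ² = 1; the factorized model cannot, which is
the statistical signature of hinge–hinge correlation.
"""

import numpy as np

from fibriflex import (mc_generate, bin_pij, gen_alpha_histogram,
                       PriorWeights, FitConfig, fit_general, fit_independent,
                       chi2_confidence_threshold)

samples = mc_generate(200_000, seed=3)
pij = bin_pij(samples)

rng = np.random.default_rng(5)
far_pairs = [k for k, (i, j) in enumerate(pij.pairs)
             if abs(i // pij.grid.n_phi - j // pij.grid.n_phi) == 2]
true_w = np.zeros(len(pij.pairs))
true_w[far_pairs] = rng.dirichlet(np.ones(len(far_pairs)))

hist = gen_alpha_histogram(true_w, pij, n_tot=4000, seed=8, model="general")
print(f"synthetic histogram: {hist.n_tot:.0f} counts from correlated "
      f"(bent × unbent) hinge-pair weights")

prior = PriorWeights.uniform(pij)
cfg = FitConfig(dof=25)
res_g = fit_general(hist, pij, prior, cfg)
res_i = fit_independent(hist, pij, prior, cfg)
thresh = chi2_confidence_threshold(cfg.dof, 0.05)

print(f"general model:      reduced χ² = {res_g.chi2:.3f} "
      f"({res_g.status}, entropy {res_g.entropy:+.3f})")
print(f"independent model:  reduced χ² = {res_i.chi2:.3f} "
      f"({res_i.status})")
print(f"5% rejection threshold at {cfg.dof} dof: χ² = {thresh:.3f}")
print("The correlated-weight data are fit perfectly by the general model "
      "but rejected under the factorized one — the same contrast used to "
      "infer hinge correlations from adsorption histograms.")
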