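"""Coarse-grained adsorption Monte Carlo and the 180° peak argument.

Samples adsorbed rod-and-sphere conformations, tabulates the conditional
α-angle distributions P_ij(α) per (γ, φ)-bin pair, and shows that the
factorized (independent-hinge) weight model always concentrates its α
distribution near 180° — the reason it cannot reproduce AFM data with a
depleted 180° region.
"""

import numpy as np

from fibriflex import (mc_generate, bin_pij, independent_peak_check,
                       two_peak_weights, model_distribution_independent)

samples = mc_generate(200_000, seed=3)
print(f"sampled {len(samples)} adsorbed conformations")
print(f"α range sampled: [{samples.alpha.min():.1f}°, "
      f"{samples.alpha.max():.1f}°]")

pij = bin_pij(samples)
n_pairs_all = pij.grid.n_bins * (pij.grid.n_bins + 1) // 2
print(f"adsorbing bin pairs: {len(pij.pairs)} of {n_pairs_all} "
      f"(the rest cannot satisfy the three-sphere contact condition)")

w2 = two_peak_weights(pij)
P = model_distribution_independent(w2, pij)
mode = pij.alpha_centers[int(np.argmax(P))]
print(f"two-peak single-hinge weight → α mode at {mode:.1f}° "
      f"(bin containing 180°)")

modes = independent_peak_check(pij, n_draws=50, seed=1)
frac = np.mean(modes >= 175.0)
print(f"random weight battery: {frac:.0%} of draws put the mode in the "
      f"180° bin (modes span {modes.min():.1f}°–{modes.max():.1f}°)")
print("Factorized hinge weights pile α mass at 180°; observed adsorption "
      "data with a 180° trough therefore require correlated hinges.")
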