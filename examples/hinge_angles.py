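"""Measure hinge bending/torsion angles and their PCA signature.

Builds a rigid three-domain chain whose bending angle γ oscillates between
the crystal-like extended form (γ ≈ 160°) and a strongly bent one
(γ ≈ 90°), recovers the angle series from the coordinates, and shows that
the dominant PCA mode of the Cα fluctuations tracks the bending.
"""

import numpy as np

from fibriflex import (HingedTrajectorySpec, gen_hinged_trajectory,
                       synthetic_hinge_specs, angle_timeseries, pca,
                       projection_combination_correlation)

n_frames = 200
gamma_script = 125.0 + 35.0 * np.sin(np.linspace(0, 6 * np.pi, n_frames))
phi_script = 20.0 * np.cos(np.linspace(0, 3 * np.pi, n_frames))

traj = gen_hinged_trajectory(HingedTrajectorySpec(
    n_frames=n_frames, gamma=gamma_script, phi=phi_script,
    sigma=0.05, seed=1, cloud_points=8))

series = angle_timeseries(traj, synthetic_hinge_specs(1))
gamma = np.array([row[0].gamma for row in series])
phi = np.array([row[0].phi for row in series])

print(f"γ recovered: mean {gamma.mean():.1f}°, range "
      f"[{gamma.min():.1f}°, {gamma.max():.1f}°] "
      f"(prescribed 90°–160°, σ = 0.05 jitter)")
print(f"φ recovered: range [{phi.min():.1f}°, {phi.max():.1f}°]")

result = pca(traj)
var_frac = result.eigenvalues[:3] / result.eigenvalues.sum()
print(f"top-3 PCA mode variance fractions: "
      f"{', '.join(f'{v:.2f}' for v in var_frac)}")

r = projection_combination_correlation(result.projections, [1.0], gamma)
print(f"correlation of PCA projection 1 with γ(t): r = {r:+.3f}")
print("A |r| close to 1 means the dominant collective motion IS the hinge "
      "bending, which is how bending is identified in real trajectories.")
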