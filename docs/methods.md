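# Methods

`fibriflex` implements a pipeline for analysing the internal flexibility of
fibrinogen (Fg): hinge-angle geometry and essential dynamics of Cα
trajectories, a coarse-grained model of the molecule adsorbed on a flat
surface, maximum-entropy fitting of hinge-weight models to AFM-style
angle histograms, and linear-mutual-information (LMI) correlation
networks. This note records the models, the parameters that matter, the
numerical choices, and the limits of what the synthetic-data tests show.

## Hinge geometry

Fibrinogen is an elongated dimer: two globular D regions joined to a
central E region by coiled-coils, each coiled-coil carrying a flexible
hinge near its middle. Bending at a hinge is described by two angles:

* **γ** (bending): the interior angle at the hinge-region centroid between
  the centroids of an E-region atom group and a D-region atom group;
  degrees in [0, 180], 180° = fully extended. The crystallographic
  protomer sits near 160°.
* **φ** (torsion): the signed IUPAC dihedral of four group centroids (two
  E-region sub-groups, the hinge, the D region); degrees in (−180, 180].

Centroids are unweighted means over Cα atoms — the one atom type present
in every structure and trajectory format we read; a mass-weighted all-atom
centroid is available via the `masses` argument of `group_centroid`. The
bundled group definitions for the human Fg protomer (chains Aα, Bβ, γ)
are: E region α50–58/β82–90/γ23–31; hinge α99–110/β130–155/γ70–100;
D region β200–458/γ140–394; the two E sub-groups of the φ definition both
include γ23–31, exactly as published. No sign convention for φ is
standard in this context; we use the IUPAC convention throughout (verified
against MDAnalysis's dihedral routine in the tests).

PCA of Cα fluctuations uses iterated superposition: every frame is Kabsch-
fitted to the running mean and the mean re-estimated until its RMS change
drops below 10⁻⁶ (coordinate units). The similarity of two essential
subspaces is the overlap O = (1/n)ΣᵢΣⱼ(xᵢ·yⱼ)², which is 1 for coincident
n-dimensional subspaces and 0 for orthogonal ones.

A residue counts as α-helical in a frame when its backbone dihedrals fall
in φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°); the window is a configuration
constant of `helicity.helical_flags` because secondary-structure
assignment conventions differ and the statistic of interest — the trend of
helicity with the bending angle — is insensitive to the exact boundary.
The helicity-vs-bending statistic defaults to 10° γ bins over [60°, 180°].

## Coarse-grained adsorption model

The molecule is reduced to a stiff central rod with the E sphere at its
center, a hinge at each rod end, and a D sphere on a short arm at each
hinge. The four hinge angles (γ₁, φ₁, γ₂, φ₂) are the only internal
degrees of freedom. Default dimensions (nm), chosen from the published
overall dimensions of the molecule and overridable via `CGGeometry` or
`build_geometry` (centroid distances and radii of gyration of labelled
atom groups):

| parameter | default | meaning |
|---|---|---|
| `rod_half_length` | 8.0 | E center to either hinge |
| `arm_length` | 8.5 | hinge to D-sphere center |
| `r_e` | 2.5 | E-sphere radius |
| `r_d` | 3.3 | D-sphere radius |
| `h_max` | 1.1·`r_d` | adsorption height threshold (sphere-to-plane gap) |

The adsorbing surface is the plane z = 0. Torsions are measured from the
downward vertical through the E center (the reference point x₀ on the
E-sphere surface is its contact point with the plane), with **per-hinge
local frames** whose azimuthal orientations are images of each other under
the molecule's C2 symmetry. This matters: with one shared lab-frame
azimuth, "both hinges at the same (γ, φ)" would *not* be the symmetric
conformation, and the symmetric conformation is exactly the one that
projects to α = 180°. "Contact" during placement means sphere-center
height equals the sphere radius; the separate adsorption predicate then
tests that all three spheres' gaps are below `h_max` and both hinges are
above the surface.

The Monte-Carlo sampler generates an adsorbed conformation by drawing
(γ₁, φ₁) and γ₂ uniformly, solving the rod tilt θ so that E and D1 touch
the plane (the contact condition is A·sinθ + B·cosθ = C, giving at most
two closed-form roots; a valid root is chosen uniformly), and solving φ₂
so that D2 touches as well (linear in cos φ₂; the ± root is chosen
uniformly). Conformations with no solution are rejected; (γ, φ)-bin pairs
that never produce a solution are recorded as non-adsorbing. Both tilt
roots and both φ₂ signs are genuine adsorbed conformations, so the uniform
choice reproduces the full ensemble in distribution.

The single-hinge (γ, φ) plane is partitioned into 12 rectangular bins:
γ edges 60/100/140/180° (the 40°-wide γ classes used to analyse fitted
weights) by four 90° φ bins; bins are right-closed ("60 < γ ≤ 100"). The
φ edge layout is not canonical; the default aligns edges with the
down/horizontal/up symmetry axes of the adsorption geometry and is
configurable in `BinGrid`.

Two stratification modes split the sample budget:

* `stratify="pairs"` (default): equal quota per admissible ordered bin
  pair, so every conditional P_ij(α) is estimated with the same
  statistical quality. Since the P_ij enter every downstream model only
  as conditionals, this is the right default for table building.
* `stratify="bins"`: Sinkhorn-balanced quotas making the per-hinge bin
  occupancy uniform over admitting bins. A caveat discovered during
  development: in this geometry both-torsions-downward bin pairs cannot
  adsorb (the D radius exceeds the E radius, so one hinge must sit low
  whenever the other reaches down), and with that admissibility pattern
  *exactly* uniform per-hinge margins are only achievable by starving all
  same-bin pairs. Use this mode when uniform occupancy itself is the
  quantity of interest, not the P_ij tables.

`bin_pij` tabulates P_ij(α) per unordered pair (5° α bins over [0°, 180°]
by default; pass the experimental edges when fitting measured histograms).
Because φ₂ is solved rather than drawn, raw accepted angles are far from
uniform within their bins; following the acceptance rule that the hinge
angles be uniformly distributed at both hinges, each ordered pair cell is
reweighted by iterative proportional fitting (6×9 subgrid per bin, 8
rounds) until both hinges' within-bin (γ, φ) marginals are flat. Raw
histograms are available with `flatten_within_bins=False`.

## The α angle and the 180° argument

α is what AFM sees: project the three region centers onto the surface and
measure the angle at the E projection; α ∈ [0, 180]. The observable
distribution is modelled as a mixture over bin pairs, P(α) = Σ a_ij
P_ij(α) in general, with the factorized (independent-hinge) special case
a_ij = a_i·a_j restricted to adsorbing pairs and renormalized.

For the factorized model, symmetric contributions (both hinges sampling
the same conformation) accumulate on the single-sided peak at α = 180°,
so its α distribution is expected to peak there for any single-hinge
weight function. With the 12-bin discretization and 5° α bins this holds
for every concentrated weight we test (delta weights on each admitting
bin, symmetric two-peak constructions) and for roughly nine out of ten
diffuse Dirichlet-random weight vectors; for the remainder, broad
cross-γ-pair peaks near 130–170° can exceed the 180° bin by a few percent
of the peak height. This is a genuine discretization effect — it is
stable from 10⁶ to 4·10⁶ Monte-Carlo samples and across plausible sphere
radii — and it is consistent with the known slight depression of the
discretized factorized fit at 180°. The qualitative conclusion is
unaffected: the factorized model can never place its maximum far from
180°, so it cannot reproduce adsorption data whose 180° region is deeply
depleted.

## Maximum-entropy fitting

Weights are estimated by maximizing the relative entropy −Σ a log(a/m) to
a prior bias m (pair bias m_ij = w_i·w_j from single-hinge occupancies
w_i) subject to normalization and the constraint that the reduced

    χ² = Σ_α (N(α) − N_tot·P(α))² / (N_tot·P(α)) / dof

equal 1. The equality is implemented as the inequality χ² ≤ 1: if the
prior already satisfies it the prior is returned (`status =
"prior_feasible"`); if even the χ²-minimizing weights violate it the
minimizer is returned with `converged = False`
(`"constraint_unreachable"`) — that is the regime in which a model family
is rejected, compared against the 5%-confidence threshold
χ²₀.₉₅(dof)/dof.

The dual over the χ² multiplier λ is solved by bracketing and bisection
(λ up to 10⁸, convergence |χ² − 1| < 10⁻³); each inner problem —
minimize KL(a‖m) + λ·χ²(a) on the simplex, which is convex for the
general model — is solved by L-BFGS in softmax coordinates with an
analytic gradient, so weights remain strictly positive by construction
and results are bit-reproducible for identical inputs. The independent
model's inner problem (quadratic mixture, non-convex) uses the same
scheme with finite-difference gradients over its ≤ 12 coordinates,
initialized at the prior.

Degrees of freedom default to (number of α bins the mixture can populate)
− 1. Subtracting the free parameter count as well is available via
`FitConfig(count_free_params=True)`, but it is degenerate for the general
model, whose ~50–60 pair weights exceed the ~30 populated 5° α bins.
χ² sums run over populated bins only; a histogram with counts in a bin
that no P_ij can reach is rejected as unfittable up front.

## LMI networks and pathways

For residues i, j with mean-subtracted Cα fluctuations, LMI(i,j) =
½(ln det Cᵢ + ln det Cⱼ − ln det Cᵢⱼ) in nats, with Cᵢ the 3×3 marginal
and Cᵢⱼ the 6×6 joint covariance. Both covariances are mean-subtracted
(required for translation invariance). LMI is clipped at 0 from below;
pairs with singular joint covariance (perfectly dependent coordinates)
are flagged infinite and excluded from networks with a warning. Frames
are superposed with the same iterated Kabsch scheme as PCA unless the
input is already a fluctuation ensemble (`superpose_frames=False`, used
with the Gaussian generator so the closed-form oracle applies exactly).

The residue network connects pairs with LMI > r_crit (the threshold is
applied to the LMI value itself). Shortest pathways between source and
target residue sets retain all tied shortest paths; paths longer than the
largest N with r_critᴺ > 0.025 are discarded (N = 22 at r_crit = 0.85,
always computed from the formula). Traversal fractions are reported both
pooled over all retained paths and averaged per (source, target) pair —
the two reasonable conventions for "fraction of pathways" — and the
bottleneck is the set of residues on every retained path. `threshold_scan`
lowers r_crit stepwise from a start value and reports the first value at
which the sets connect; `control_pairs` lists residue pairs at least a
minimum distance apart (6 nm for the published control) for control
enumerations.

## Synthetic data

* **Hinged trajectories**: rigid point-cloud domains (≥ 4 non-coplanar
  points each) placed so that the measured (γ, φ) reproduce a prescribed
  script exactly at zero jitter; per-atom isotropic Gaussian jitter (no
  temporal autocorrelation) is added after placement. One or two hinges;
  writes standard PDB/DCD via MDAnalysis.
* **Gaussian trajectories**: i.i.d. frames from a specified 3R×3R
  covariance (PSD-checked), matching the model underlying the LMI
  estimator exactly.
* **α histograms**: multinomial draws from a general or factorized
  mixture over a P_ij table.
* **Backbone windows**: ideal-geometry N/CA/C chains built from (φ, ψ)
  scripts (ω = 180°), for helicity tests.

All generators are deterministic under a seed and attach provenance
metadata. What passing tests show — and do not show: the generators match
the estimators' model assumptions by construction (rigid domains,
i.i.d. Gaussian fluctuations, no autocorrelation, exact multinomial
sampling), so the tests validate the estimators and fitting machinery,
not their robustness to real-data pathologies (anharmonicity, correlated
noise, partial occupancy, force-field artifacts).

## Problem sizes and determinism

Default study sizes: 10⁶ Monte-Carlo conformations for a converged P_ij
table (about 15 s on one core; the sampler is vectorized per bin-pair
batch), N_tot = 1000 for histogram-fit recoveries, 10⁴ frames for
Gaussian LMI checks, 50-node graphs for pathway enumeration oracles.
Larger Monte-Carlo runs sharpen the P_ij tails but do not change any
conclusion reported here (checked at 4·10⁶). Every stochastic component
takes an explicit integer seed; fits are deterministic given inputs.

## Known limitations

* The coarse-grained model has no excluded volume beyond the height
  tests, and no αC regions or βN stretches.
* The crystal-derived default geometry uses published overall dimensions;
  deriving it from an actual structure file is supported through
  `build_geometry` with the bundled group definitions.
* The factorized-model 180° mode is exact for concentrated weights but
  can be displaced by a few bins for very diffuse weights, as discussed
  above.
* The fitted-weight uncertainty is not estimated (no bootstrap); the χ²
  machinery quantifies goodness of fit only.
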