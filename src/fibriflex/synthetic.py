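"""Synthetic trajectory and histogram generators.

Three generators produce inputs with exactly the statistical structure the
analysis stages assume, so every stage can be validated without MD output
or experimental AFM data:

* :func:`gen_hinged_trajectory` — a rigid three-domain Cα chain whose
  hinge angles follow a prescribed (γ(t), φ(t)) script, with optional
  isotropic per-atom jitter;
* :func:`gen_gaussian_trajectory` — i.i.d. frames from a multivariate
  normal with a specified 3R×3R covariance (the model underlying the
  linear-mutual-information estimator);
* :func:`gen_alpha_histogram` — multinomial α-angle counts drawn from a
  known hinge-weight mixture model.

All generators are deterministic under a fixed seed and attach provenance
metadata (the spec and seed) to their output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .trajectory import Trajectory
from .geometry import AtomGroupSpec, HingeSpec
from .cg import PijTable
from .maxent import AlphaHistogram, model_distribution_general, \
    model_distribution_independent

__all__ = ["HingedTrajectorySpec", "GaussianTrajectorySpec",
           "gen_hinged_trajectory", "gen_gaussian_trajectory",
           "gen_alpha_histogram", "synthetic_hinge_specs",
           "gen_backbone_trajectory", "attach_backbone", "block_covariance"]


def _cloud(scale: float = 0.3, n_points: int = 4) -> np.ndarray:
    """Zero-mean non-coplanar point template (rigid-domain stand-in).

    The first four points form a tetrahedron; additional points (fixed,
    seeded) keep the centroid at zero.
    """
    tet = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                    [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
    if n_points < 4:
        raise ValueError("a rigid domain needs at least 4 points")
    if n_points > 4:
        extra = np.random.default_rng(1234).uniform(-1, 1, (n_points - 4, 3))
        tet = np.concatenate([tet, extra])
        tet = tet - tet.mean(axis=0)
    return scale * tet


# centroid layout of the rigid central assembly (x along the rod):
# γ-group E on the axis at the origin; per hinge k an off-axis and an
# on-axis φ reference group, the hinge cloud, and the D arm of length _ARM
_ROD = 6.0          # center to hinge
_ARM = 5.0          # hinge to D centroid
_G1_OFF = (1.5, 2.0)  # (|x| toward hinge, y) of the off-axis φ group
_G2_X = 3.0           # |x| of the on-axis φ group

# chain ids of the generated groups, hinge 1 then hinge 2
_CHAINS = {"E": "E",
           1: {"g1": "F", "g2": "G", "hinge": "H", "d": "I"},
           2: {"g1": "J", "g2": "K", "hinge": "L", "d": "M"}}


def synthetic_hinge_specs(n_hinges: int = 1) -> list[HingeSpec]:
    """Group specs measuring the generated hinges (γ from E/hinge/D
    centroids, φ from the four-group dihedral)."""
    out = []
    rng = (1, 9999)  # whole chain, whatever the cloud size
    for k in range(1, n_hinges + 1):
        ch = _CHAINS[k]
        e = AtomGroupSpec("E region", [(_CHAINS["E"], rng)])
        g1 = AtomGroupSpec("E part 1", [(ch["g1"], rng)])
        g2 = AtomGroupSpec("E part 2", [(ch["g2"], rng)])
        h = AtomGroupSpec("hinge", [(ch["hinge"], rng)])
        d = AtomGroupSpec("D region", [(ch["d"], rng)])
        out.append(HingeSpec(gamma_groups=(e, h, d), phi_groups=(g1, g2, h, d)))
    return out


@dataclass
class HingedTrajectorySpec:
    """Prescription for a rigid-body hinged Cα trajectory.

    ``gamma``/``phi`` are scalars or per-frame arrays for hinge 1;
    ``gamma2``/``phi2`` likewise for the optional second hinge.  ``sigma``
    is the isotropic per-atom jitter applied after rigid placement (no
    temporal autocorrelation).
    """

    n_frames: int
    gamma: object = 160.0
    phi: object = 0.0
    gamma2: object = None
    phi2: object = None
    sigma: float = 0.0
    seed: int = 0
    cloud_scale: float = 0.3
    cloud_points: int = 4

    @property
    def n_hinges(self) -> int:
        return 2 if self.gamma2 is not None else 1


def _series(x, n: int, name: str, lo: float, hi: float,
            closed_low: bool = True) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, float), (n,)).copy()
    bad = (arr < lo) | (arr > hi) | ((arr == lo) & ~closed_low)
    if np.any(bad):
        raise ValueError(f"{name} script leaves its valid range [{lo}, {hi}]")
    return arr


def _min_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180° flip about any axis perpendicular to a
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, p)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def gen_hinged_trajectory(spec: HingedTrajectorySpec) -> Trajectory:
    """Cα trajectory of a rigid three-domain chain with scripted hinges.

    With ``sigma = 0`` the measured (γ, φ) reproduce the prescription to
    numerical precision; jitter adds unbiased per-atom noise whose effect
    on the centroid angles shrinks with group size.
    """
    n = spec.n_frames
    g1 = _series(spec.gamma, n, "gamma", 0.0, 180.0)
    p1 = _series(spec.phi, n, "phi", -180.0, 180.0, closed_low=False)
    if spec.n_hinges == 2:
        g2 = _series(spec.gamma2, n, "gamma2", 0.0, 180.0)
        p2 = _series(0.0 if spec.phi2 is None else spec.phi2, n, "phi2",
                     -180.0, 180.0, closed_low=False)
    rng = np.random.default_rng(spec.seed)
    tmpl = _cloud(spec.cloud_scale, spec.cloud_points)

    # static central assembly: per hinge sign s (−1 toward hinge 1)
    def centroids(s):
        return {"g1": np.array([s * _G1_OFF[0], _G1_OFF[1], 0.0]),
                "g2": np.array([s * _G2_X, 0.0, 0.0]),
                "hinge": np.array([s * _ROD, 0.0, 0.0])}

    chains, resids, names = [], [], []
    static_parts = [("E", _CHAINS["E"], np.zeros(3))]
    hinge_sides = [(1, -1.0)] + ([(2, 1.0)] if spec.n_hinges == 2 else [])
    for k, s in hinge_sides:
        cen = centroids(s)
        for key in ("g1", "g2", "hinge"):
            static_parts.append((key, _CHAINS[k][key], cen[key]))
    static_coords = np.concatenate([tmpl + c for _, _, c in static_parts])
    for _, ch, _c in static_parts:
        chains += [ch] * len(tmpl)
        resids += list(range(1, len(tmpl) + 1))
        names += ["CA"] * len(tmpl)
    for k, _s in hinge_sides:
        chains += [_CHAINS[k]["d"]] * len(tmpl)
        resids += list(range(1, len(tmpl) + 1))
        names += ["CA"] * len(tmpl)

    frames = np.empty((n, len(chains), 3))
    d2r = np.pi / 180.0
    for f in range(n):
        arms = []
        for (k, s) in hinge_sides:
            g = (g1 if k == 1 else g2)[f] * d2r
            # sign of the φ azimuth calibrated so the measured IUPAC
            # dihedral of (g1, g2, hinge, D) equals the prescription
            p = _PHI_SIGN[k] * (p1 if k == 1 else p2)[f] * d2r
            hinge_c = np.array([s * _ROD, 0.0, 0.0])
            u = np.array([-s * np.cos(g),
                          np.sin(g) * np.cos(p),
                          np.sin(g) * np.sin(p)])
            d_cent = hinge_c + _ARM * u
            R = _min_rotation(np.array([1.0, 0.0, 0.0]), u)
            arms.append(tmpl @ R.T + d_cent)
        frames[f] = np.concatenate([static_coords] + arms)
    if spec.sigma > 0:
        frames += rng.normal(0.0, spec.sigma, frames.shape)
    traj = Trajectory(coords=frames, chain_ids=np.array(chains, object),
                      resids=np.array(resids), atom_names=np.array(names, object))
    traj.meta = {"generator": "gen_hinged_trajectory", "seed": spec.seed,
                 "spec": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in asdict(spec).items()}}
    return traj


# azimuth sign per hinge making the generated dihedral match the IUPAC
# convention of geometry.torsion_angle (the two arms are mirror images)
_PHI_SIGN = {1: -1.0, 2: 1.0}


@dataclass
class GaussianTrajectorySpec:
    """Multivariate-normal Cα fluctuations around a base structure."""

    n_residues: int
    covariance: np.ndarray        # (3R, 3R) symmetric PSD
    n_frames: int
    seed: int = 0
    base: np.ndarray | None = None  # (R, 3); default: chain along x, 1.0 apart


def block_covariance(n_residues: int, variance: float = 1.0,
                     cross: dict | None = None) -> np.ndarray:
    """Convenience 3R×3R covariance: isotropic per-residue blocks
    ``variance``·I₃ plus isotropic cross blocks ρ·I₃ from
    ``cross = {(i, j): rho}``."""
    R = n_residues
    C = np.kron(np.eye(R) * variance, np.eye(3))
    if cross:
        for (i, j), rho in cross.items():
            blk = float(rho) * np.eye(3)
            C[3 * i:3 * i + 3, 3 * j:3 * j + 3] = blk
            C[3 * j:3 * j + 3, 3 * i:3 * i + 3] = blk
    return C


def gen_gaussian_trajectory(spec: GaussianTrajectorySpec) -> Trajectory:
    """Frames drawn i.i.d. from N(base, covariance).

    The empirical covariance converges to the specification as the frame
    count grows; a non-positive-semi-definite covariance is rejected.
    """
    R = spec.n_residues
    C = np.asarray(spec.covariance, float)
    if C.shape != (3 * R, 3 * R):
        raise ValueError(f"covariance must be {3 * R}x{3 * R}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    evals = np.linalg.eigvalsh(C)
    if evals.min() < -1e-10 * max(evals.max(), 1.0):
        raise ValueError("covariance is not positive semi-definite")
    base = spec.base
    if base is None:
        base = np.zeros((R, 3))
        base[:, 0] = np.arange(R, dtype=float)
    rng = np.random.default_rng(spec.seed)
    dev = rng.multivariate_normal(np.zeros(3 * R), C, size=spec.n_frames,
                                  method="eigh")
    coords = base[None] + dev.reshape(spec.n_frames, R, 3)
    traj = Trajectory(coords=coords,
                      chain_ids=np.array(["A"] * R, object),
                      resids=np.arange(1, R + 1),
                      atom_names=np.array(["CA"] * R, object))
    traj.meta = {"generator": "gen_gaussian_trajectory", "seed": spec.seed,
                 "n_residues": R, "n_frames": spec.n_frames}
    return traj


def gen_alpha_histogram(weights, pij: PijTable, n_tot: int, seed: int = 0,
                        model: str = "general") -> AlphaHistogram:
    """Multinomial α histogram of ``n_tot`` counts from a mixture model.

    ``model`` selects the weight convention: "general" pair weights a_ij
    (aligned with ``pij.pairs`` or a {(i,j): w} dict) or "independent"
    single-hinge weights a_i.
    """
    if n_tot < 1:
        raise ValueError("n_tot must be at least 1")
    if model == "general":
        P = model_distribution_general(weights, pij)
    elif model == "independent":
        P = model_distribution_independent(weights, pij)
    else:
        raise ValueError(f"unknown model kind {model!r}")
    P = np.maximum(P, 0)
    P = P / P.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_tot, P)
    hist = AlphaHistogram(edges=np.asarray(pij.alpha_edges, float),
                          counts=counts.astype(float))
    hist.meta = {"generator": "gen_alpha_histogram", "seed": seed,
                 "model": model, "n_tot": int(n_tot)}
    return hist


# ---------------------------------------------------------------------------
# ideal-geometry backbone builder (for helicity tests)

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}
HELIX_PHI_PSI = (-60.0, -45.0)
COIL_PHI_PSI = (-120.0, 130.0)


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place the next atom from three predecessors and internal coordinates."""
    th = np.radians(angle_deg)
    ta = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(th),
                  bond * np.sin(th) * np.cos(ta),
                  bond * np.sin(th) * np.sin(ta)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def gen_backbone_trajectory(phi_psi: np.ndarray, chain_id: str = "W",
                            ) -> Trajectory:
    """Backbone (N, CA, C) chain built from per-frame (φ, ψ) prescriptions.

    ``phi_psi`` has shape (n_frames, n_residues, 2) in degrees; one
    flanking residue is added at each end so every window residue has both
    dihedrals defined.  ω is fixed at 180°.
    """
    phi_psi = np.asarray(phi_psi, float)
    F, nres, _ = phi_psi.shape
    total = nres + 2
    frames = np.empty((F, 3 * total, 3))
    for f in range(F):
        phis = np.concatenate([[COIL_PHI_PSI[0]], phi_psi[f, :, 0],
                               [COIL_PHI_PSI[0]]])
        psis = np.concatenate([[COIL_PHI_PSI[1]], phi_psi[f, :, 1],
                               [COIL_PHI_PSI[1]]])
        atoms = [np.array([0.0, 0.0, 0.0]),
                 np.array([_BOND["N-CA"], 0.0, 0.0])]
        th = np.radians(_ANGLE["N-CA-C"])
        atoms.append(atoms[1] + _BOND["CA-C"] *
                     np.array([-np.cos(th), np.sin(th), 0.0]))
        for i in range(1, total):
            n_i = _nerf(atoms[-3], atoms[-2], atoms[-1], _BOND["C-N"],
                        _ANGLE["CA-C-N"], psis[i - 1])
            atoms.append(n_i)
            ca_i = _nerf(atoms[-3], atoms[-2], atoms[-1], _BOND["N-CA"],
                         _ANGLE["C-N-CA"], 180.0)
            atoms.append(ca_i)
            c_i = _nerf(atoms[-3], atoms[-2], atoms[-1], _BOND["CA-C"],
                        _ANGLE["N-CA-C"], phis[i])
            atoms.append(c_i)
        frames[f] = np.asarray(atoms)
    chains = np.array([chain_id] * (3 * total), object)
    resids = np.repeat(np.arange(1, total + 1), 3)
    names = np.array(["N", "CA", "C"] * total, object)
    return Trajectory(coords=frames, chain_ids=chains, resids=resids,
                      atom_names=names)


def attach_backbone(traj: Trajectory, phi_psi: np.ndarray,
                    chain_id: str = "W", offset: float = 50.0) -> Trajectory:
    """Concatenate a scripted backbone window onto an existing trajectory
    (same frame count), displaced by ``offset`` along z to avoid overlap."""
    bb = gen_backbone_trajectory(phi_psi, chain_id=chain_id)
    if bb.n_frames != traj.n_frames:
        raise ValueError("frame counts differ")
    coords = np.concatenate([traj.coords,
                             bb.coords + np.array([0.0, 0.0, offset])], axis=1)
    return Trajectory(coords=coords,
                      chain_ids=np.concatenate([traj.chain_ids, bb.chain_ids]),
                      resids=np.concatenate([traj.resids, bb.resids]),
                      atom_names=np.concatenate([traj.atom_names, bb.atom_names]))
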