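"""Per-residue helicity from backbone dihedrals and its coupling to bending.

A residue is counted as α-helical in a frame when its backbone (φ, ψ)
dihedrals fall inside a rectangular Ramachandran window (default
φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°)).  The joint statistic of interest is
the probability distribution of the helical fraction of a residue window —
e.g. the three residues either side of the plasmin cleavage sites
Aα104–105 and Bβ133–134 — as a function of the hinge bending angle γ:
stronger bending (lower γ) disrupting the coiled-coil shows up as a
negative trend of mean helicity with decreasing γ.
"""

from __future__ import annotations

import numpy as np

from .geometry import _dihedral
from .trajectory import Trajectory

__all__ = ["HELICAL_PHI_RANGE", "HELICAL_PSI_RANGE", "backbone_dihedrals",
           "helical_flags", "helicity_bending_histogram", "helicity_vs_bending",
           "default_gamma_edges"]

HELICAL_PHI_RANGE = (-100.0, -30.0)
HELICAL_PSI_RANGE = (-80.0, -5.0)


def default_gamma_edges() -> np.ndarray:
    """10° bins over [60°, 180°]."""
    return np.arange(60.0, 180.0 + 1e-9, 10.0)


def backbone_dihedrals(traj: Trajectory, chain_id: str,
                       resid_range: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(φ, ψ) per frame per residue of the window, degrees.

    Requires N, CA, C atoms for the window residues plus the flanking
    residues (φ needs C of the residue before, ψ the N of the one after).
    """
    lo, hi = resid_range
    need = range(lo - 1, hi + 2)
    atom_idx = {}
    for rid in need:
        for name in ("N", "CA", "C"):
            sel = (traj.chain_ids == chain_id) & (traj.resids == rid) & (traj.atom_names == name)
            j = np.nonzero(sel)[0]
            if j.size:
                atom_idx[(rid, name)] = j[0]
    nres = hi - lo + 1
    phi = np.full((traj.n_frames, nres), np.nan)
    psi = np.full((traj.n_frames, nres), np.nan)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        for k, rid in enumerate(range(lo, hi + 1)):
            try:
                c_prev = frame[atom_idx[(rid - 1, "C")]]
                n = frame[atom_idx[(rid, "N")]]
                ca = frame[atom_idx[(rid, "CA")]]
                c = frame[atom_idx[(rid, "C")]]
                n_next = frame[atom_idx[(rid + 1, "N")]]
            except KeyError as err:
                raise KeyError(
                    f"backbone atoms missing around chain {chain_id} residue {rid}: "
                    f"{err.args[0]}") from None
            phi[f, k] = _dihedral(c_prev, n, ca, c)
            psi[f, k] = _dihedral(n, ca, c, n_next)
    return phi, psi


def helical_flags(phi: np.ndarray, psi: np.ndarray,
                  phi_range: tuple[float, float] = HELICAL_PHI_RANGE,
                  psi_range: tuple[float, float] = HELICAL_PSI_RANGE) -> np.ndarray:
    """Boolean helicity per (frame, residue) from (φ, ψ) arrays in degrees."""
    return ((phi > phi_range[0]) & (phi < phi_range[1])
            & (psi > psi_range[0]) & (psi < psi_range[1]))


def helicity_bending_histogram(gamma: np.ndarray, helical_fraction: np.ndarray,
                               gamma_edges: np.ndarray | None = None,
                               fraction_edges: np.ndarray | None = None
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint probability table over (γ bin, helical-fraction bin).

    Returns (table, gamma_edges, fraction_edges); the table is normalized to
    total mass 1 over the frames that fall inside the γ range.
    """
    gamma = np.asarray(gamma, float)
    frac = np.asarray(helical_fraction, float)
    if gamma.shape != frac.shape:
        raise ValueError("gamma and helical_fraction must be per-frame series "
                         "of equal length")
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("helical fractions must lie in [0, 1]")
    if gamma_edges is None:
        gamma_edges = default_gamma_edges()
    if fraction_edges is None:
        fraction_edges = np.linspace(0.0, 1.0, 11)
    H, ge, fe = np.histogram2d(gamma, frac, bins=[gamma_edges, fraction_edges])
    total = H.sum()
    if total > 0:
        H = H / total
    return H, ge, fe


def helicity_vs_bending(traj: Trajectory, window: tuple[str, tuple[int, int]],
                        gamma_series: np.ndarray,
                        gamma_edges: np.ndarray | None = None,
                        fraction_edges: np.ndarray | None = None):
    """Joint (γ, helical fraction) table for one backbone residue window.

    ``window`` is (chain_id, (first_resid, last_resid)); ``gamma_series`` is
    the per-frame bending angle measured on the same trajectory (see
    :func:`fibriflex.geometry.angle_timeseries`).
    """
    phi, psi = backbone_dihedrals(traj, *window)
    frac = helical_flags(phi, psi).mean(axis=1)
    return helicity_bending_histogram(gamma_series, frac, gamma_edges, fraction_edges)
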