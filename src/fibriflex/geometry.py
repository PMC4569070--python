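"""Hinge bending and torsion angles from atom-group centroids.

The bending angle γ of the fibrinogen coiled-coil hinge is the interior
angle at the hinge-region centroid between the centroids of an E-region
group and a D-region group; the torsion angle φ is the signed dihedral of
four group centroids (two E-region sub-groups, the hinge, the D region),
with the IUPAC sign convention.  γ = 180° is the fully extended molecule
seen in the crystal structures; simulations reach γ below 90°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory, SelectionError

__all__ = [
    "AtomGroupSpec", "HingeAngles", "HingeSpec", "DegenerateGeometryError",
    "group_centroid", "bending_angle", "torsion_angle", "angle_timeseries",
    "FG_GAMMA_GROUPS", "FG_PHI_GROUPS",
]


class DegenerateGeometryError(ValueError):
    """Coincident or collinear centroids make the angle undefined."""


@dataclass(frozen=True)
class AtomGroupSpec:
    """A named group of Cα atoms given as (chain, residue-range) selections.

    Residue ranges are 1-based and inclusive, e.g. the E-region group is
    ``[("A", (50, 58)), ("B", (82, 90)), ("C", (23, 31))]`` for chains
    Aα, Bβ, γ of one fibrinogen protomer.
    """

    label: str
    selections: tuple = ()
    atom_names: tuple | None = ("CA",)

    def __post_init__(self):
        object.__setattr__(self, "selections", tuple(
            (str(c), (int(lo), int(hi))) for c, (lo, hi) in self.selections))
        if not self.selections:
            raise ValueError(f"group {self.label!r} has no selections")
        for _, (lo, hi) in self.selections:
            if lo > hi:
                raise ValueError(f"group {self.label!r}: empty range {lo}–{hi}")

    def resolve(self, traj: Trajectory) -> np.ndarray:
        """Atom indices of the group; raises SelectionError naming any missing range."""
        parts = []
        for chain, rng in self.selections:
            try:
                parts.append(traj.select(chain, rng, names=self.atom_names))
            except SelectionError as err:
                raise SelectionError(
                    f"group {self.label!r}: {err.args[0]}") from None
        return np.unique(np.concatenate(parts))


@dataclass(frozen=True)
class HingeAngles:
    """One (γ, φ) pair in degrees: γ ∈ [0, 180], φ ∈ (−180, 180]."""

    gamma: float
    phi: float

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 180.0:
            raise ValueError(f"gamma {self.gamma} outside [0, 180]")
        if not -180.0 < self.phi <= 180.0:
            raise ValueError(f"phi {self.phi} outside (-180, 180]")


@dataclass(frozen=True)
class HingeSpec:
    """Group specs measuring one hinge: three for γ, four for φ.

    ``phi_groups`` may be None when only bending is of interest.
    """

    gamma_groups: tuple  # (e_spec, hinge_spec, d_spec)
    phi_groups: tuple | None = None  # (g1, g2, g3, g4)


# Atom groups of the fibrinogen protomer hinge (chains Aα="A", Bβ="B", γ="C").
# The φ definition's first two groups both include γ23–31, as published.
_E = AtomGroupSpec("E region", [("A", (50, 58)), ("B", (82, 90)), ("C", (23, 31))])
_HINGE = AtomGroupSpec("hinge region", [("A", (99, 110)), ("B", (130, 155)), ("C", (70, 100))])
_D = AtomGroupSpec("D region", [("B", (200, 458)), ("C", (140, 394))])
FG_GAMMA_GROUPS = (_E, _HINGE, _D)
FG_PHI_GROUPS = (
    AtomGroupSpec("E part 1", [("A", (50, 58)), ("C", (23, 31))]),
    AtomGroupSpec("E part 2", [("B", (82, 90)), ("C", (23, 31))]),
    _HINGE,
    _D,
)


def group_centroid(frame: np.ndarray, traj: Trajectory, spec: AtomGroupSpec,
                   masses: np.ndarray | None = None) -> np.ndarray:
    """Centroid of a group's atoms in one coordinate frame.

    Unweighted mean of the selected Cα positions by default; pass per-atom
    ``masses`` for a mass-weighted (all-atom) centroid.
    """
    idx = spec.resolve(traj)
    pts = np.asarray(frame, dtype=float)[idx]
    if masses is None:
        return pts.mean(axis=0)
    w = np.asarray(masses, dtype=float)[idx]
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def _angle_at(b: np.ndarray, a: np.ndarray, c: np.ndarray) -> float:
    """Interior angle at ``a`` between rays to ``b`` and ``c``, degrees."""
    u, v = b - a, c - a
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("coincident centroids")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _dihedral(p1, p2, p3, p4) -> float:
    """IUPAC signed dihedral of four points, degrees in (−180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear centroid triple")
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(y, np.dot(n1, n2))))
    return 180.0 if ang <= -180.0 else ang


def bending_angle(frame: np.ndarray, traj: Trajectory,
                  e_spec: AtomGroupSpec, hinge_spec: AtomGroupSpec,
                  d_spec: AtomGroupSpec) -> float:
    """Bending angle γ (degrees) at the hinge centroid, in [0, 180]."""
    e = group_centroid(frame, traj, e_spec)
    h = group_centroid(frame, traj, hinge_spec)
    d = group_centroid(frame, traj, d_spec)
    return _angle_at(e, h, d)


def torsion_angle(frame: np.ndarray, traj: Trajectory,
                  g1: AtomGroupSpec, g2: AtomGroupSpec,
                  g3: AtomGroupSpec, g4: AtomGroupSpec) -> float:
    """Torsion angle φ (degrees): signed dihedral of four group centroids."""
    pts = [group_centroid(frame, traj, g) for g in (g1, g2, g3, g4)]
    return _dihedral(*pts)


def angle_timeseries(traj: Trajectory, hinges: list[HingeSpec] | HingeSpec,
                     ) -> list[list[HingeAngles]]:
    """Per-frame (γ, φ) pairs for each hinge, order preserved.

    Returns a list with one entry per frame; each entry is a list of
    :class:`HingeAngles`, one per hinge spec.  When a hinge spec has no φ
    groups, φ is reported as 0.
    """
    if isinstance(hinges, HingeSpec):
        hinges = [hinges]
    # resolve selections once; also validates them against the topology
    resolved = []
    for h in hinges:
        g_idx = [g.resolve(traj) for g in h.gamma_groups]
        p_idx = ([g.resolve(traj) for g in h.phi_groups]
                 if h.phi_groups is not None else None)
        resolved.append((g_idx, p_idx))
    out = []
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        row = []
        for g_idx, p_idx in resolved:
            e, h_, d = (frame[i].mean(axis=0) for i in g_idx)
            gamma = _angle_at(e, h_, d)
            if p_idx is not None:
                try:
                    phi = _dihedral(*(frame[i].mean(axis=0) for i in p_idx))
                except DegenerateGeometryError:
                    phi = 0.0  # torsion undefined at a fully straight hinge
            else:
                phi = 0.0
            row.append(HingeAngles(gamma=gamma, phi=phi))
        out.append(row)
    return out
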