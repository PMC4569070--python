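"""Rod-and-sphere model of adsorbed fibrinogen and the adsorption Monte Carlo.

The molecule is reduced to a stiff central rod (the two coiled-coil
regions) carrying the E sphere at its center and a hinge at each end; each
hinge carries a short rod ending in a D sphere.  The four hinge angles
(γ1, φ1, γ2, φ2) are the only internal degrees of freedom.  The adsorbing
surface is the plane z = 0; torsions are measured from the downward
vertical through the E center (the reference point x0 on the E-sphere
surface is its lowest point).

Adsorption requires the E and both D spheres to sit within a height
threshold h_max of the surface with both hinges above it.  The Monte Carlo
sampler generates adsorbed conformations by drawing (γ1, φ1) and γ2,
tilting the central rod so that E and D1 touch the surface, and solving
the torsion φ2 so that D2 touches as well; acceptance is stratified so
that the per-hinge (γ, φ) bin occupancy is uniform over the bins that
admit adsorption.  The conditional α-angle distributions P_ij(α) — α being
the angle between the surface projections of the three globular regions,
as seen by AFM — are then tabulated per unordered bin pair (i, j).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CGGeometry", "CGConformation", "BinGrid", "MCSamples", "PijTable",
           "build_geometry", "place_conformation", "measure_angles",
           "is_adsorbed", "measure_alpha", "mc_generate", "bin_pij",
           "default_alpha_edges", "DEFAULT_GEOMETRY"]

_D2R = np.pi / 180.0


class DegenerateProjectionError(ValueError):
    pass


@dataclass(frozen=True)
class CGGeometry:
    """Dimensions of the rod-and-sphere model, in nm.

    rod_half_length: E center to either hinge; arm_length: hinge to D
    center; r_e / r_d: radii of the E and D spheres; h_max: adsorption
    height threshold applied to the sphere-to-surface gap.
    """

    rod_half_length: float = 8.0
    arm_length: float = 8.5
    r_e: float = 2.5
    r_d: float = 3.3
    h_max: float = None

    def __post_init__(self):
        if self.h_max is None:
            object.__setattr__(self, "h_max", 1.1 * self.r_d)
        for name in ("rod_half_length", "arm_length", "r_e", "r_d", "h_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def x0(self) -> np.ndarray:
        """Torsion reference point on the E-sphere surface: its lowest point.

        With the E center at (0, 0, r_e) in the surface frame this is the
        contact point with the plane, so φ = 0 points a D arm straight down.
        """
        return np.zeros(3)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: getattr(self, k) for k in
                       ("rod_half_length", "arm_length", "r_e", "r_d", "h_max")},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "CGGeometry":
        with open(path) as fh:
            return cls(**json.load(fh))


DEFAULT_GEOMETRY = CGGeometry()


def _radius_of_gyration(pts: np.ndarray) -> float:
    pts = np.asarray(pts, float)
    c = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1))))


def build_geometry(groups: dict, h_max: float | None = None,
                   h_max_factor: float = 1.1) -> CGGeometry:
    """Extract model dimensions from labelled coordinate groups.

    ``groups`` maps labels "E", "hinge1", "D1" (and optionally "hinge2",
    "D2") to (n, 3) coordinate arrays; rod lengths are centroid distances
    and sphere radii are radii of gyration, averaged over the two
    symmetric halves when both are present.
    """
    for key in ("E", "hinge1", "D1"):
        if key not in groups:
            raise KeyError(f"missing group {key!r}")
    cent = {k: np.asarray(v, float).mean(axis=0) for k, v in groups.items()}
    halves = [("hinge1", "D1")]
    if "hinge2" in groups and "D2" in groups:
        halves.append(("hinge2", "D2"))
    rod = float(np.mean([np.linalg.norm(cent[h] - cent["E"]) for h, _ in halves]))
    arm = float(np.mean([np.linalg.norm(cent[d] - cent[h]) for h, d in halves]))
    r_e = _radius_of_gyration(groups["E"])
    r_d = float(np.mean([_radius_of_gyration(groups[d]) for _, d in halves]))
    if h_max is None:
        h_max = h_max_factor * r_d
    return CGGeometry(rod_half_length=rod, arm_length=arm, r_e=r_e, r_d=r_d,
                      h_max=h_max)


@dataclass
class CGConformation:
    """Hinge angles plus the derived 3-D embedding (surface frame, z=0 plane)."""

    gamma1: float
    phi1: float
    gamma2: float
    phi2: float
    e_center: np.ndarray
    d1_center: np.ndarray
    d2_center: np.ndarray
    hinge1: np.ndarray
    hinge2: np.ndarray
    adsorbed: bool = False


def _frame_vectors(theta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rod axis r̂ (tilt θ from horizontal, in the xz-plane) and the
    perpendicular pair (d̂ = downward reference, b̂ = r̂ × d̂)."""
    ct, st = np.cos(theta), np.sin(theta)
    r = np.array([ct, 0.0, st])
    d = np.array([st, 0.0, -ct])
    b = np.array([0.0, 1.0, 0.0])
    return r, d, b


def _embed(gamma1, phi1, gamma2, phi2, geom: CGGeometry, theta: float = 0.0):
    """Place the five model points for given hinge angles and rod tilt."""
    g1, p1 = gamma1 * _D2R, phi1 * _D2R
    g2, p2 = gamma2 * _D2R, phi2 * _D2R
    r, d, b = _frame_vectors(theta)
    L, l = geom.rod_half_length, geom.arm_length
    e = np.array([0.0, 0.0, geom.r_e])
    h1, h2 = e - L * r, e + L * r
    # per-hinge local frames: outward axis â_k, shared downward reference d̂,
    # b̂_k = â_k × d̂ — so equal (γ, φ) at both hinges is the C2-symmetric
    # conformation (which projects to α = 180°)
    u1 = np.cos(g1) * r + np.sin(g1) * (np.cos(p1) * d - np.sin(p1) * b)
    u2 = -np.cos(g2) * r + np.sin(g2) * (np.cos(p2) * d + np.sin(p2) * b)
    return e, h1 + l * u1, h2 + l * u2, h1, h2


def place_conformation(gamma1: float, phi1: float, gamma2: float, phi2: float,
                       geom: CGGeometry = DEFAULT_GEOMETRY,
                       theta: float = 0.0) -> CGConformation:
    """Deterministic embedding of hinge angles into 3-D.

    The central rod lies in the xz-plane tilted by ``theta`` from
    horizontal (0 = canonical, rod along x), the E sphere touches the
    z = 0 plane, and each D arm is bent off the rod by (180° − γ) and
    swung about it by φ measured from the downward reference direction.
    """
    for g in (gamma1, gamma2):
        if not 0.0 <= g <= 180.0:
            raise ValueError(f"gamma {g} outside [0, 180]")
    for p in (phi1, phi2):
        if not -180.0 < p <= 180.0:
            raise ValueError(f"phi {p} outside (-180, 180]")
    e, d1, d2, h1, h2 = _embed(gamma1, phi1, gamma2, phi2, geom, theta)
    conf = CGConformation(gamma1, phi1, gamma2, phi2, e, d1, d2, h1, h2)
    conf.adsorbed = is_adsorbed(conf, geom)
    return conf


def _wrap_phi(deg: float) -> float:
    w = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if w <= -180.0 else w


def measure_angles(conf: CGConformation) -> tuple[float, float, float, float]:
    """Recover (γ1, φ1, γ2, φ2) in degrees from the embedded points."""
    e = conf.e_center
    r = conf.hinge2 - e
    r = r / np.linalg.norm(r)
    down = np.array([0.0, 0.0, -1.0])
    d = down - np.dot(down, r) * r
    nd = np.linalg.norm(d)
    if nd < 1e-12:  # vertical rod: reference direction undefined
        d = np.array([1.0, 0.0, 0.0])
    else:
        d = d / nd
    b = np.cross(r, d)
    out = []
    # hinge-local azimuth frames (see _embed): b̂1 = −b̂, b̂2 = +b̂
    for hinge, dcent, sign in ((conf.hinge1, conf.d1_center, 1.0),
                               (conf.hinge2, conf.d2_center, -1.0)):
        u = dcent - hinge
        u = u / np.linalg.norm(u)
        cosg = np.clip(sign * np.dot(u, r), -1.0, 1.0)
        gamma = np.degrees(np.arccos(cosg))
        w = u - np.dot(u, r) * r
        if np.linalg.norm(w) < 1e-9:
            phi = 0.0
        else:
            phi = np.degrees(np.arctan2(-sign * np.dot(w, b), np.dot(w, d)))
        out.extend([float(gamma), _wrap_phi(float(phi))])
    return tuple(out)


def is_adsorbed(conf: CGConformation, geom: CGGeometry = DEFAULT_GEOMETRY) -> bool:
    """Adsorption test: all three globular regions within h_max of the
    surface (sphere-to-plane gap) and both hinges above the surface."""
    gaps = (conf.e_center[2] - geom.r_e,
            conf.d1_center[2] - geom.r_d,
            conf.d2_center[2] - geom.r_d)
    hinges_ok = conf.hinge1[2] >= 0.0 and conf.hinge2[2] >= 0.0
    return bool(all(g < geom.h_max for g in gaps) and hinges_ok)


def measure_alpha(conf: CGConformation) -> float:
    """The AFM-observable angle α ∈ [0, 180]: project the three region
    centers on the surface, measure the angle at the E projection."""
    v1 = conf.d1_center[:2] - conf.e_center[:2]
    v2 = conf.d2_center[:2] - conf.e_center[:2]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateProjectionError("projected D coincides with projected E")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass(frozen=True)
class BinGrid:
    """Rectangular partition of the single-hinge (γ, φ) plane.

    Bins are right-closed ("60° < γ ≤ 100°" style).  The default grid —
    γ edges 60/100/140/180° by four 90°-wide φ bins — has 12 bins.
    """

    gamma_edges: tuple = (60.0, 100.0, 140.0, 180.0)
    phi_edges: tuple = (-180.0, -90.0, 0.0, 90.0, 180.0)

    def __post_init__(self):
        ge = np.asarray(self.gamma_edges, float)
        pe = np.asarray(self.phi_edges, float)
        if np.any(np.diff(ge) <= 0) or np.any(np.diff(pe) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "gamma_edges", tuple(ge))
        object.__setattr__(self, "phi_edges", tuple(pe))

    @property
    def n_gamma(self) -> int:
        return len(self.gamma_edges) - 1

    @property
    def n_phi(self) -> int:
        return len(self.phi_edges) - 1

    @property
    def n_bins(self) -> int:
        return self.n_gamma * self.n_phi

    def bin_index(self, gamma, phi):
        """Flat bin index for (γ, φ) arrays; -1 outside the grid."""
        gamma = np.asarray(gamma, float)
        phi = np.asarray(phi, float)
        gi = np.searchsorted(self.gamma_edges, gamma, side="left") - 1
        gi = np.where(gamma == self.gamma_edges[0], 0, gi)
        pi = np.searchsorted(self.phi_edges, phi, side="left") - 1
        pi = np.where(phi == self.phi_edges[0], 0, pi)
        ok = (gi >= 0) & (gi < self.n_gamma) & (pi >= 0) & (pi < self.n_phi)
        return np.where(ok, gi * self.n_phi + pi, -1)

    def bin_ranges(self, k: int):
        """((γ_lo, γ_hi), (φ_lo, φ_hi)) of flat bin k."""
        gi, pi = divmod(int(k), self.n_phi)
        return ((self.gamma_edges[gi], self.gamma_edges[gi + 1]),
                (self.phi_edges[pi], self.phi_edges[pi + 1]))


@dataclass
class MCSamples:
    """Columnar store of accepted adsorbed conformations."""

    gamma1: np.ndarray
    phi1: np.ndarray
    gamma2: np.ndarray
    phi2: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    bin1: np.ndarray
    bin2: np.ndarray
    grid: BinGrid = field(default_factory=BinGrid)

    def __len__(self) -> int:
        return self.gamma1.size

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({k: getattr(self, k) for k in
                             ("gamma1", "phi1", "gamma2", "phi2", "theta",
                              "alpha", "bin1", "bin2")})


def _attempt_batch(rng, geom: CGGeometry, grid: BinGrid, i: int, j: int, m: int):
    """Vectorized batch of m placement attempts targeting ordered bin pair
    (hinge1 in bin i, hinge2 in bin j).  Returns columns of accepted rows."""
    (g1lo, g1hi), (p1lo, p1hi) = grid.bin_ranges(i)
    (g2lo, g2hi), (p2lo, p2hi) = grid.bin_ranges(j)
    L, l = geom.rod_half_length, geom.arm_length
    re_, rd = geom.r_e, geom.r_d

    gamma1 = rng.uniform(g1lo, g1hi, m)
    phi1 = rng.uniform(p1lo, p1hi, m)
    gamma2 = rng.uniform(g2lo, g2hi, m)
    g1, p1, g2 = gamma1 * _D2R, phi1 * _D2R, gamma2 * _D2R

    # rod tilt from E + D1 contact: A sinθ + B cosθ = C
    A = l * np.cos(g1) - L
    B = -l * np.sin(g1) * np.cos(p1)
    C = rd - re_
    R = np.hypot(A, B)
    with np.errstate(invalid="ignore"):
        s = np.arcsin(np.clip(C / np.where(R > 0, R, np.nan), -1.0, 1.0))
    delta = np.arctan2(B, A)
    cand = np.stack([s - delta, np.pi - s - delta], axis=1)
    cand = (cand + np.pi) % (2 * np.pi) - np.pi
    sin_t = np.sin(cand)
    valid = (np.abs(cand) < 0.5 * np.pi - 1e-9) & (np.abs(sin_t) <= re_ / L) \
        & np.isfinite(cand) & (R[:, None] >= np.abs(C) - 1e-12)
    # verify the contact equation (guards arcsin branch issues)
    resid = A[:, None] * np.sin(cand) + B[:, None] * np.cos(cand) - C
    valid &= np.abs(resid) < 1e-9 * max(1.0, L + l)
    n_valid = valid.sum(axis=1)
    pick = rng.integers(0, 2, m)
    first_valid = np.argmax(valid, axis=1)
    both = n_valid == 2
    choice = np.where(both, pick, first_valid)
    theta = cand[np.arange(m), choice]
    ok = n_valid > 0

    # torsion at hinge 2 from D2 contact
    st, ct = np.sin(theta), np.cos(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        cphi2 = (re_ + L * st - l * np.cos(g2) * st - rd) / (l * np.sin(g2) * ct)
    ok &= np.isfinite(cphi2) & (np.abs(cphi2) <= 1.0)
    sign = np.where(rng.integers(0, 2, m) == 0, 1.0, -1.0)
    phi2 = np.degrees(sign * np.arccos(np.clip(cphi2, -1.0, 1.0)))
    # right-closed bin membership for hinge 2's φ
    in_j = (phi2 > p2lo) & (phi2 <= p2hi)
    ok &= in_j

    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        return None
    g1a, p1a, g2a = g1[idx], p1[idx], g2[idx]
    p2deg = phi2[idx]
    p2a = p2deg * _D2R
    th = theta[idx]
    st, ct = np.sin(th), np.cos(th)
    # α from the projected region centers (E at the xy-origin)
    # D1 = E - L r̂ + l u1 ; D2 = E + L r̂ + l u2 with the frame of _embed
    rx = ct
    dx = st
    u1x = np.cos(g1a) * rx + np.sin(g1a) * np.cos(p1a) * dx
    u1y = -np.sin(g1a) * np.sin(p1a)  # b̂1 = −b̂ (hinge-local frame)
    u2x = -np.cos(g2a) * rx + np.sin(g2a) * np.cos(p2a) * dx
    u2y = np.sin(g2a) * np.sin(p2a)
    v1 = np.stack([-L * rx + l * u1x, l * u1y], axis=1)
    v2 = np.stack([L * rx + l * u2x, l * u2y], axis=1)
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    keep = (n1 > 1e-9) & (n2 > 1e-9)
    cosa = np.clip(np.sum(v1[keep] * v2[keep], axis=1) / (n1[keep] * n2[keep]),
                   -1.0, 1.0)
    alpha = np.degrees(np.arccos(cosa))
    idx = idx[keep]
    return (gamma1[idx], phi1[idx], gamma2[idx], p2deg[keep], th[keep], alpha)


def _balanced_quotas(admissible: np.ndarray, n: int) -> np.ndarray:
    """Symmetric per-ordered-pair quotas with (near-)uniform bin margins.

    Sinkhorn-style scaling of the admissibility indicator toward equal row
    sums; rows with no admissible partner stay empty.
    """
    A = admissible.astype(float)
    active = A.sum(axis=1) > 0
    Q = A.copy()
    for _ in range(500):
        rs = Q.sum(axis=1)
        scale = np.ones_like(rs)
        scale[active] = 1.0 / rs[active]
        S = np.sqrt(np.outer(scale, scale))
        Q = Q * S
        if np.allclose(Q.sum(axis=1)[active], 1.0, atol=1e-10):
            break
    tot = Q.sum()
    if tot <= 0:
        raise RuntimeError("no adsorbing bin pair found")
    quotas = np.floor(n * Q / tot).astype(int)
    # distribute the rounding remainder over the largest entries
    short = n - quotas.sum()
    if short > 0:
        order = np.argsort(-(n * Q / tot - quotas), axis=None)
        for k in order[:short]:
            quotas[np.unravel_index(k, Q.shape)] += 1
    return quotas


def mc_generate(n: int, geom: CGGeometry = DEFAULT_GEOMETRY,
                grid: BinGrid | None = None, seed: int = 0,
                stratify: str = "pairs", probe: int = 400,
                attempt_factor: int = 1000) -> MCSamples:
    """Generate ``n`` adsorbed conformations, stratified over bin pairs.

    A probe round finds the ordered bin pairs that admit adsorption, then
    the sample budget is split over them by ``stratify``:

    * ``"pairs"`` (default): equal quota per admissible ordered pair, so
      every conditional P_ij(α) is tabulated with the same statistical
      quality;
    * ``"bins"``: Sinkhorn-balanced quotas making the per-hinge (γ, φ)
      bin occupancy uniform over the admitting bins.  Note that with this
      geometry the non-adsorbing pattern makes exactly uniform margins
      concentrate the budget on cross pairs (same-bin pairs receive almost
      none), so use ``"pairs"`` when the P_ij table is the goal.

    Pairs whose quota cannot be filled within ``attempt_factor`` × quota
    attempts are reported in a warning.  Deterministic under ``seed``.
    """
    if grid is None:
        grid = BinGrid()
    rng = np.random.default_rng(seed)
    nb = grid.n_bins
    cols = {k: [] for k in ("gamma1", "phi1", "gamma2", "phi2", "theta",
                            "alpha", "bin1", "bin2")}
    if n == 0:
        return MCSamples(*(np.empty(0) for _ in range(6)),
                         np.empty(0, int), np.empty(0, int), grid)

    admissible = np.zeros((nb, nb), dtype=bool)
    for i in range(nb):
        for j in range(nb):
            res = _attempt_batch(rng, geom, grid, i, j, probe)
            if res is not None and res[0].size > 0:
                admissible[i, j] = True
    # admissibility is a property of the unordered pair; symmetrize so a
    # rare ordered direction missed by the probe does not break it
    admissible |= admissible.T

    if stratify == "bins":
        quotas = _balanced_quotas(admissible, n)
    elif stratify == "pairs":
        k = int(admissible.sum())
        if k == 0:
            raise RuntimeError("no adsorbing bin pair found")
        quotas = np.zeros((nb, nb), dtype=int)
        quotas[admissible] = n // k
        rem = n - quotas.sum()
        ij = np.argwhere(admissible)
        for r in range(rem):
            quotas[tuple(ij[r % len(ij)])] += 1
    else:
        raise ValueError(f"unknown stratify mode {stratify!r}")
    starved = []
    for i in range(nb):
        for j in range(nb):
            q = quotas[i, j]
            if q == 0:
                continue
            got = 0
            attempts = 0
            budget = attempt_factor * q
            while got < q and attempts < budget:
                m = min(max(4 * (q - got), 256), 200_000)
                attempts += m
                res = _attempt_batch(rng, geom, grid, i, j, m)
                if res is None:
                    continue
                g1, p1, g2, p2, th, al = res
                take = min(q - got, g1.size)
                got += take
                cols["gamma1"].append(g1[:take])
                cols["phi1"].append(p1[:take])
                cols["gamma2"].append(g2[:take])
                cols["phi2"].append(p2[:take])
                cols["theta"].append(th[:take])
                cols["alpha"].append(al[:take])
                cols["bin1"].append(np.full(take, i, int))
                cols["bin2"].append(np.full(take, j, int))
            if got < q:
                starved.append(((i, j), got, q))
    if starved:
        warnings.warn("starved bin pairs (pair, got, quota): "
                      + ", ".join(map(str, starved)), RuntimeWarning)
    arrs = {k: (np.concatenate(v) if v else np.empty(0)) for k, v in cols.items()}
    arrs["bin1"] = arrs["bin1"].astype(int)
    arrs["bin2"] = arrs["bin2"].astype(int)
    return MCSamples(grid=grid, **arrs)


def default_alpha_edges(width: float = 5.0) -> np.ndarray:
    """α histogram edges, 5° bins over [0°, 180°] by default."""
    return np.arange(0.0, 180.0 + 1e-9, width)


@dataclass
class PijTable:
    """Conditional α distributions per unordered (γ, φ)-bin pair.

    ``hist[k]`` is the normalized α histogram of unordered pair
    ``pairs[k]``; pairs never observed among the adsorbed samples are
    masked non-adsorbing and carry no histogram.
    """

    alpha_edges: np.ndarray              # (n_alpha+1,)
    pairs: list                          # [(i, j) with i <= j]
    hist: np.ndarray                     # (n_pairs, n_alpha), rows sum to 1
    counts: np.ndarray                   # (n_pairs,) samples per pair
    grid: BinGrid

    _index: dict = field(default=None, repr=False)

    def __post_init__(self):
        self._index = {p: k for k, p in enumerate(self.pairs)}

    @property
    def n_alpha(self) -> int:
        return len(self.alpha_edges) - 1

    @property
    def alpha_centers(self) -> np.ndarray:
        e = np.asarray(self.alpha_edges, float)
        return 0.5 * (e[1:] + e[:-1])

    def pair_key(self, i: int, j: int) -> tuple[int, int]:
        return (i, j) if i <= j else (j, i)

    def is_adsorbing(self, i: int, j: int) -> bool:
        return self.pair_key(i, j) in self._index

    def p_alpha(self, i: int, j: int) -> np.ndarray:
        """P_ij(α); symmetric in (i, j).  KeyError on a masked pair."""
        return self.hist[self._index[self.pair_key(i, j)]]

    @property
    def adsorbing_bins(self) -> np.ndarray:
        """Sorted single-hinge bins that occur in at least one adsorbing pair."""
        return np.unique([b for p in self.pairs for b in p])

    def occupancy_weights(self) -> np.ndarray:
        """Single-hinge bin weights w_i from the sample counts (pooled over
        both hinges), normalized over all grid bins."""
        w = np.zeros(self.grid.n_bins)
        for (i, j), c in zip(self.pairs, self.counts):
            w[i] += c
            w[j] += c
        return w / w.sum()

    def to_json(self, path: str) -> None:
        obj = {"alpha_edges": list(map(float, self.alpha_edges)),
               "gamma_edges": list(self.grid.gamma_edges),
               "phi_edges": list(self.grid.phi_edges),
               "pairs": [list(map(int, p)) for p in self.pairs],
               "hist": self.hist.tolist(),
               "counts": self.counts.tolist()}
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str) -> "PijTable":
        with open(path) as fh:
            obj = json.load(fh)
        grid = BinGrid(tuple(obj["gamma_edges"]), tuple(obj["phi_edges"]))
        return cls(alpha_edges=np.asarray(obj["alpha_edges"]),
                   pairs=[tuple(p) for p in obj["pairs"]],
                   hist=np.asarray(obj["hist"], float),
                   counts=np.asarray(obj["counts"], int), grid=grid)


def _flatten_weights(samples: MCSamples, grid: BinGrid,
                     n_sub_gamma: int = 6, n_sub_phi: int = 9,
                     n_iter: int = 8) -> np.ndarray:
    """Per-sample weights flattening the within-bin (γ, φ) marginals.

    The sampler draws (γ1, φ1, γ2) flat but solves φ2 from the contact
    condition, so the accepted angles are not uniform within their bins.
    Following the acceptance rule that the hinge-angle distribution be
    uniform at both hinges, each ordered bin-pair cell is reweighted by
    iterative proportional fitting on a subgrid until both hinges'
    within-bin (γ, φ) marginals are flat.
    """
    w_all = np.ones(len(samples))

    def sub(vals, lo, hi, n):
        return np.clip(((vals - lo) / (hi - lo) * n).astype(int), 0, n - 1)

    for i in range(grid.n_bins):
        for j in range(grid.n_bins):
            sel = np.nonzero((samples.bin1 == i) & (samples.bin2 == j))[0]
            if sel.size == 0:
                continue
            (g1lo, g1hi), (p1lo, p1hi) = grid.bin_ranges(i)
            (g2lo, g2hi), (p2lo, p2hi) = grid.bin_ranges(j)
            c1 = (sub(samples.gamma1[sel], g1lo, g1hi, n_sub_gamma) * n_sub_phi
                  + sub(samples.phi1[sel], p1lo, p1hi, n_sub_phi))
            c2 = (sub(samples.gamma2[sel], g2lo, g2hi, n_sub_gamma) * n_sub_phi
                  + sub(samples.phi2[sel], p2lo, p2hi, n_sub_phi))
            m = n_sub_gamma * n_sub_phi
            w = np.ones(sel.size)
            for _ in range(n_iter):
                h1 = np.bincount(c1, weights=w, minlength=m)
                w *= np.where(h1[c1] > 0, 1.0 / np.maximum(h1[c1], 1e-12), 0.0)
                h2 = np.bincount(c2, weights=w, minlength=m)
                w *= np.where(h2[c2] > 0, 1.0 / np.maximum(h2[c2], 1e-12), 0.0)
            w_all[sel] = w / w.mean()
    return w_all


def bin_pij(samples: MCSamples, grid: BinGrid | None = None,
            alpha_edges: np.ndarray | None = None,
            flatten_within_bins: bool = True) -> PijTable:
    """Tabulate P_ij(α) from MC samples, symmetrized over (i,j)/(j,i).

    With ``flatten_within_bins`` (default) the α histograms are weighted
    so that the within-bin hinge-angle marginals are uniform at both
    hinges (see :func:`_flatten_weights`); otherwise raw counts are used.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    if grid is None:
        grid = samples.grid
    if alpha_edges is None:
        alpha_edges = default_alpha_edges()
    alpha_edges = np.asarray(alpha_edges, float)
    weights = (_flatten_weights(samples, grid) if flatten_within_bins
               else np.ones(len(samples)))
    lo = np.minimum(samples.bin1, samples.bin2)
    hi = np.maximum(samples.bin1, samples.bin2)
    pairs = sorted(set(zip(lo.tolist(), hi.tolist())))
    hist = np.zeros((len(pairs), len(alpha_edges) - 1))
    counts = np.zeros(len(pairs), dtype=int)
    for k, (i, j) in enumerate(pairs):
        sel = (lo == i) & (hi == j)
        h, _ = np.histogram(samples.alpha[sel], bins=alpha_edges,
                            weights=weights[sel])
        counts[k] = int(sel.sum())
        if h.sum() > 0:
            hist[k] = h / h.sum()
    keep = counts > 0
    pairs = [p for p, k in zip(pairs, keep) if k]
    table = PijTable(alpha_edges=alpha_edges, pairs=pairs, hist=hist[keep],
                     counts=counts[keep], grid=grid)
    if np.all(table.hist.sum(axis=0) == 0):
        warnings.warn("all α bins empty", RuntimeWarning)
    return table
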