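"""Linear mutual information networks and correlated-motion pathways.

For two residues with Cα fluctuation vectors x_i, x_j (3-D, mean
subtracted) the linear mutual information is

    LMI(x_i, x_j) = ½ (ln det C_i + ln det C_j − ln det C_ij)     [nats]

with C_i the 3×3 marginal and C_ij the 6×6 joint covariance.  LMI is
non-negative, zero for linearly independent motions, and diverges when
the joint covariance is singular (perfectly dependent coordinates); such
pairs are flagged infinite and excluded from the network.

A residue graph connects pairs whose LMI exceeds a threshold r_crit; the
shortest paths in that graph between two binding sites trace the pathway
of correlated motion.  Paths longer than the largest N with
r_crit**N > 0.025 are discarded; residues on all retained paths form the
bottleneck of the allosteric network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx

from .pca import superpose

__all__ = ["LMIMatrix", "PathwayResult", "lmi_matrix", "max_path_length",
           "build_network", "find_pathways", "threshold_scan", "control_pairs"]


@dataclass
class LMIMatrix:
    """Symmetric residue-pair LMI values plus the covariance blocks."""

    values: np.ndarray        # (R, R), nan on the diagonal, inf on singular pairs
    residue_cov: np.ndarray   # (R, 3, 3) per-residue covariance blocks C_i

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def finite_pairs(self):
        R = self.n_residues
        return [(i, j) for i in range(R) for j in range(i + 1, R)
                if np.isfinite(self.values[i, j])]

    def to_csv(self, path: str, labels=None) -> None:
        import pandas as pd
        if labels is None:
            labels = [str(i) for i in range(self.n_residues)]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str) -> "LMIMatrix":
        import pandas as pd
        vals = pd.read_csv(path, index_col=0).to_numpy(dtype=float)
        return cls(values=vals, residue_cov=np.full((vals.shape[0], 3, 3), np.nan))


def lmi_matrix(traj, superpose_frames: bool = True,
               min_frames_factor: int = 10, singular_tol: float = 1e-12
               ) -> LMIMatrix:
    """LMI for every residue pair of a Cα trajectory.

    ``traj`` is a :class:`~fibriflex.trajectory.Trajectory` (one Cα per
    residue) or an (n_frames, n_residues, 3) array.  Frames are superposed
    with the iterated Kabsch scheme unless ``superpose_frames`` is False
    (synthetic, already-aligned fluctuations).  Pairs with singular joint
    covariance come out infinite.
    """
    coords = traj.coords if hasattr(traj, "coords") else np.asarray(traj, float)
    F, R, _ = coords.shape
    if F < min_frames_factor * 6:
        raise ValueError(
            f"need at least {min_frames_factor * 6} frames for 6-D covariances, "
            f"got {F}")
    X = superpose(coords) if superpose_frames else np.asarray(coords, float)
    X = X - X.mean(axis=0)                       # (F, R, 3), mean subtracted
    flat = X.reshape(F, 3 * R)
    C = (flat.T @ flat) / (F - 1)                # full 3R×3R covariance
    blocks = np.array([C[3 * i:3 * i + 3, 3 * i:3 * i + 3] for i in range(R)])
    sign_i, logdet_i = np.linalg.slogdet(blocks)
    vals = np.full((R, R), np.nan)
    singular = 0
    for i in range(R):
        for j in range(i + 1, R):
            idx = np.r_[3 * i:3 * i + 3, 3 * j:3 * j + 3]
            Cij = C[np.ix_(idx, idx)]
            s, ld = np.linalg.slogdet(Cij)
            if s <= 0 or np.linalg.det(Cij) < singular_tol * max(
                    np.linalg.det(blocks[i]) * np.linalg.det(blocks[j]), 1e-300):
                vals[i, j] = vals[j, i] = np.inf
                singular += 1
                continue
            lmi = 0.5 * (logdet_i[i] + logdet_i[j] - ld)
            vals[i, j] = vals[j, i] = max(lmi, 0.0)  # clip small negatives
    if singular:
        import warnings
        warnings.warn(f"{singular} residue pair(s) have singular joint "
                      "covariance; flagged infinite and excluded from networks",
                      RuntimeWarning)
    return LMIMatrix(values=vals, residue_cov=blocks)


def max_path_length(r_crit: float, floor: float = 0.025) -> int:
    """Largest integer N with r_crit**N > floor (the path-length cutoff)."""
    if not 0 < r_crit:
        raise ValueError("r_crit must be positive")
    if r_crit >= 1.0:
        return np.iinfo(np.int32).max
    n = int(np.floor(np.log(floor) / np.log(r_crit)))
    while r_crit ** n <= floor:
        n -= 1
    while r_crit ** (n + 1) > floor:
        n += 1
    return n


def build_network(lmi: LMIMatrix, r_crit: float) -> nx.Graph:
    """Undirected residue graph: edge iff LMI > r_crit (finite pairs only)."""
    if r_crit <= 0:
        raise ValueError("r_crit must be positive")
    R = lmi.n_residues
    G = nx.Graph()
    G.add_nodes_from(range(R))
    vals = lmi.values
    for i in range(R):
        for j in range(i + 1, R):
            v = vals[i, j]
            if np.isfinite(v) and v > r_crit:
                G.add_edge(i, j)
    return G


@dataclass
class PathwayResult:
    paths: list                 # residue index sequences, source → target
    fractions: dict             # residue → fraction of retained paths through it
    fractions_by_pair: dict     # residue → fraction of (source,target) pairs whose
                                # shortest paths all pass through it... see docstring
    bottleneck: list            # residues on 100% of retained paths
    max_length: int             # path-length cutoff N used

    def __bool__(self) -> bool:
        return bool(self.paths)


def find_pathways(graph: nx.Graph, sources, targets, r_crit: float,
                  floor: float = 0.025) -> PathwayResult:
    """All shortest paths between each (source, target) residue pair.

    Pairs whose shortest-path length (edges) exceeds the largest N with
    r_crit**N > ``floor`` are discarded.  Traversal fractions are reported
    in two conventions: pooled over all retained shortest paths
    (``fractions``) and averaged over (source, target) pairs
    (``fractions_by_pair``, each pair's path ensemble weighted equally).
    The bottleneck is the set of residues on every retained path.
    """
    sources, targets = list(sources), list(targets)
    if set(sources) & set(targets):
        raise ValueError("source and target sets must be disjoint")
    N = max_path_length(r_crit, floor)
    paths = []
    per_pair_fracs = []
    for s in sources:
        for t in targets:
            try:
                length = nx.shortest_path_length(graph, s, t)
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                continue
            if length > N:
                continue
            pair_paths = list(nx.all_shortest_paths(graph, s, t))
            paths.extend(pair_paths)
            counts: dict = {}
            for p in pair_paths:
                for r in set(p):
                    counts[r] = counts.get(r, 0) + 1
            per_pair_fracs.append({r: c / len(pair_paths)
                                   for r, c in counts.items()})
    if not paths:
        return PathwayResult([], {}, {}, [], N)
    counts: dict = {}
    for p in paths:
        for r in set(p):
            counts[r] = counts.get(r, 0) + 1
    n_paths = len(paths)
    fractions = {r: c / n_paths for r, c in counts.items()}
    n_pairs = len(per_pair_fracs)
    by_pair: dict = {}
    for d in per_pair_fracs:
        for r, f in d.items():
            by_pair[r] = by_pair.get(r, 0.0) + f / n_pairs
    bottleneck = sorted(r for r, f in fractions.items() if f >= 1.0)
    return PathwayResult(paths, fractions, by_pair, bottleneck, N)


def threshold_scan(lmi: LMIMatrix, sources, targets, r_start: float,
                   step: float, r_floor: float = 1e-3):
    """Scan r_crit downward from ``r_start`` in steps of ``step`` and return
    (first connecting r_crit, PathwayResult); (None, empty) if never
    connected above ``r_floor``."""
    if r_start <= 0 or step <= 0:
        raise ValueError("r_start and step must be positive")
    r = r_start
    while r > r_floor:
        G = build_network(lmi, r)
        res = find_pathways(G, sources, targets, r)
        if res:
            return r, res
        r = r - step
    return None, PathwayResult([], {}, {}, [], 0)


def control_pairs(coords: np.ndarray, min_separation: float = 6.0) -> list:
    """Residue pairs at least ``min_separation`` apart (Cα–Cα distance,
    same units as the coordinates; 6 nm for the published control)."""
    pts = np.asarray(coords, float)
    if pts.ndim == 3:  # trajectory: use first frame
        pts = pts[0]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    R = pts.shape[0]
    return [(i, j) for i in range(R) for j in range(i + 1, R)
            if d[i, j] >= min_separation]
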