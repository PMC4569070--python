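"""Principal component analysis of Cα trajectories and mode-space overlap.

PCA is performed on the Cartesian fluctuation covariance of a selected set
of atoms after iterated least-squares superposition (Kabsch fit to the
running mean, repeated until the mean structure stops changing).  The
similarity of the essential subspaces of two trajectories is quantified by
the mean squared inner products of their leading modes,

    O({x}, {y}) = (1/n) Σ_i Σ_j (x_i · y_j)²,

which is 1 when the two n-dimensional subspaces coincide and 0 when they
are orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "kabsch_rotation", "superpose", "pca",
           "subspace_overlap", "projection_combination_correlation"]


@dataclass
class PCAResult:
    mean: np.ndarray          # (n_atoms, 3) mean structure after superposition
    modes: np.ndarray         # (n_modes, 3*n_atoms) orthonormal rows, by decreasing variance
    eigenvalues: np.ndarray   # (n_modes,) variances, non-increasing
    projections: np.ndarray   # (n_frames, n_modes), zero mean per mode

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation R (3x3) minimizing |P @ R.T - Q| for centered P, Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(coords: np.ndarray, tol: float = 1e-6, max_iter: int = 100
              ) -> np.ndarray:
    """Iteratively superpose all frames onto their running mean.

    Each iteration removes the centroid of every frame, rotates it onto the
    current mean with a Kabsch fit, and recomputes the mean; iteration stops
    when the RMS change of the mean drops below ``tol`` (coordinate units).
    """
    X = np.asarray(coords, dtype=float).copy()
    X -= X.mean(axis=1, keepdims=True)
    ref = X[0].copy()
    for _ in range(max_iter):
        for f in range(X.shape[0]):
            R = kabsch_rotation(X[f], ref)
            X[f] = X[f] @ R.T
        new_ref = X.mean(axis=0)
        delta = np.sqrt(np.mean((new_ref - ref) ** 2))
        ref = new_ref
        if delta < tol:
            break
    return X


def pca(traj, selection: np.ndarray | None = None, n_modes: int | None = None,
        superpose_frames: bool = True) -> PCAResult:
    """PCA of the Cα covariance of a trajectory (or plain coordinate array).

    ``traj`` may be a :class:`~fibriflex.trajectory.Trajectory` or an
    (n_frames, n_atoms, 3) array; ``selection`` is an optional atom-index
    subset.  At most min(3*n_atoms, n_frames-1) modes carry variance; asking
    for more emits a rank warning and truncates.
    """
    import warnings

    coords = traj.coords if hasattr(traj, "coords") else np.asarray(traj, float)
    if coords.ndim != 3:
        raise ValueError("expected (n_frames, n_atoms, 3) coordinates")
    if selection is not None:
        coords = coords[:, np.asarray(selection, int), :]
    F, N, _ = coords.shape
    if F < 2:
        raise ValueError("PCA needs at least two frames")
    X = superpose(coords) if superpose_frames else np.asarray(coords, float)
    mean = X.mean(axis=0)
    flat = (X - mean).reshape(F, 3 * N)
    rank = min(3 * N, F - 1)
    if n_modes is None:
        n_modes = rank
    elif n_modes > rank:
        warnings.warn(
            f"requested {n_modes} modes but covariance rank is at most {rank}; "
            "truncating", RuntimeWarning)
        n_modes = rank
    # SVD route: eigenvalues of the covariance are s^2/(F-1)
    U, s, Vt = np.linalg.svd(flat, full_matrices=False)
    eigvals = (s ** 2) / (F - 1)
    modes = Vt[:n_modes]
    projections = flat @ modes.T
    return PCAResult(mean=mean, modes=modes, eigenvalues=eigvals[:n_modes],
                     projections=projections)


def subspace_overlap(x_modes: np.ndarray, y_modes: np.ndarray, n: int,
                     atol: float = 1e-8) -> float:
    """Overlap O = (1/n) Σ_ij (x_i · y_j)² between two orthonormal mode sets."""
    X = np.asarray(x_modes, float)[:n]
    Y = np.asarray(y_modes, float)[:n]
    if X.shape[0] < n or Y.shape[0] < n:
        raise ValueError(f"need at least n={n} modes in each set")
    if X.shape[1] != Y.shape[1]:
        raise ValueError("mode sets live in different ambient dimensions")
    for M, name in ((X, "x"), (Y, "y")):
        G = M @ M.T
        if not np.allclose(G, np.eye(n), atol=max(atol, 1e-6)):
            raise ValueError(f"{name}_modes are not orthonormal")
    S = X @ Y.T
    return float(np.sum(S ** 2) / n)


def projection_combination_correlation(projections: np.ndarray,
                                       coefficients: np.ndarray,
                                       angle_series: np.ndarray) -> float:
    """Pearson r between CP(t) = Σ_j a_j P_j(t) and an angle time series.

    ``coefficients`` has one entry per projection column; e.g. the bending
    angle tracks the combination a = (1, −1, −0.1) of the first three modes.
    """
    P = np.asarray(projections, float)
    a = np.asarray(coefficients, float)
    y = np.asarray(angle_series, float)
    cp = P[:, : a.size] @ a
    if cp.size != y.size:
        raise ValueError("series lengths differ")
    if np.std(cp) < 1e-15 or np.std(y) < 1e-15:
        raise ZeroDivisionError("zero-variance series: correlation undefined")
    return float(np.corrcoef(cp, y)[0, 1])
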