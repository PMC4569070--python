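"""Maximum-entropy fitting of hinge-weight models to α-angle histograms.

Two mixture models map single-hinge statistics to the observable α-angle
distribution of adsorbed molecules:

* general (correlated hinges):      P(α) = Σ_ij a_ij P_ij(α)
* independent hinges (factorized):  P(α) = Σ_ij a_i a_j P_ij(α)

with P_ij(α) the Monte-Carlo-derived conditional distributions per
(γ, φ)-bin pair (non-adsorbing pairs excluded, the factorized mixture
renormalized over the admissible mass).  The weights are estimated by
maximizing the relative entropy −Σ a log(a/m) to a prior bias m (built
from single-hinge bin occupancies, m_ij = w_i w_j) under the constraints
that the weights normalize and the reduced

    χ² = Σ_α (N(α) − N_tot P(α))² / (N_tot P(α)) / dof

equals 1.  The equality is treated as the inequality χ² ≤ 1: when the
prior already fits (χ²(m) ≤ 1) the prior is returned unchanged; when even
the best weights cannot reach χ² = 1 the χ²-minimizing weights are
returned with ``converged = False``.  The Lagrange dual over the χ²
multiplier λ is solved by bisection with an inner quasi-Newton solve in
softmax coordinates, so weights stay positive by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .cg import PijTable

__all__ = ["AlphaHistogram", "PriorWeights", "FitConfig", "FitResult",
           "model_distribution_general", "model_distribution_independent",
           "reduced_chi2", "chi2_unreduced", "fit_general", "fit_independent",
           "chi2_confidence_threshold", "independent_peak_check",
           "two_peak_weights"]


@dataclass
class AlphaHistogram:
    """Binned α-angle counts (the AFM observable)."""

    edges: np.ndarray   # (n_bins+1,) degrees over [0, 180]
    counts: np.ndarray  # (n_bins,) non-negative

    def __post_init__(self):
        self.edges = np.asarray(self.edges, float)
        self.counts = np.asarray(self.counts, float)
        if self.counts.size != self.edges.size - 1:
            raise ValueError("counts/edges size mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_tot(self) -> float:
        return float(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    def to_csv(self, path: str) -> None:
        import pandas as pd
        pd.DataFrame({"alpha_lo": self.edges[:-1], "alpha_hi": self.edges[1:],
                      "count": self.counts}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "AlphaHistogram":
        import pandas as pd
        df = pd.read_csv(path)
        edges = np.append(df["alpha_lo"].to_numpy(), df["alpha_hi"].iloc[-1])
        return cls(edges=edges, counts=df["count"].to_numpy())


@dataclass
class PriorWeights:
    """Single-hinge bin weights w_i and the derived pair bias m_ij = w_i w_j."""

    w: np.ndarray  # (n_grid_bins,) non-negative

    def __post_init__(self):
        self.w = np.asarray(self.w, float)
        if np.any(self.w < 0):
            raise ValueError("negative prior weight")

    @classmethod
    def uniform(cls, pij: PijTable) -> "PriorWeights":
        w = np.zeros(pij.grid.n_bins)
        bins = pij.adsorbing_bins
        w[bins] = 1.0 / bins.size
        return cls(w=w)

    @classmethod
    def from_occupancy(cls, pij: PijTable) -> "PriorWeights":
        return cls(w=pij.occupancy_weights())

    def pair_bias(self, pij: PijTable) -> np.ndarray:
        """Prior mass per unordered adsorbing pair (off-diagonal pooled),
        normalized over the adsorbing pairs."""
        m = np.array([(1.0 if i == j else 2.0) * self.w[i] * self.w[j]
                      for i, j in pij.pairs])
        tot = m.sum()
        if tot <= 0:
            raise ValueError("prior carries no mass on adsorbing pairs")
        return m / tot

    def bin_prior(self, pij: PijTable) -> np.ndarray:
        """Prior over admitting single-hinge bins, normalized."""
        bins = pij.adsorbing_bins
        w = self.w[bins]
        if w.sum() <= 0:
            raise ValueError("prior carries no mass on admitting bins")
        return w / w.sum()


def _as_pair_weights(a, pij: PijTable) -> np.ndarray:
    """Accept an array aligned with pij.pairs or a {(i,j): weight} dict."""
    if isinstance(a, dict):
        out = np.zeros(len(pij.pairs))
        for (i, j), v in a.items():
            key = pij.pair_key(i, j)
            if not pij.is_adsorbing(*key):
                raise ValueError(f"weight on non-adsorbing pair {(i, j)}")
            out[pij.pairs.index(key)] += v
        a = out
    a = np.asarray(a, float)
    if a.size != len(pij.pairs):
        raise ValueError("one weight per adsorbing pair required")
    if np.any(a < 0):
        raise ValueError("negative weight")
    return a


def model_distribution_general(a, pij: PijTable) -> np.ndarray:
    """Mixture P(α) = Σ_ij a_ij P_ij(α) over unordered adsorbing pairs."""
    a = _as_pair_weights(a, pij)
    s = a.sum()
    if not np.isclose(s, 1.0, atol=1e-8):
        raise ValueError(f"pair weights sum to {s}, expected 1")
    return pij.hist.T @ a


def _independent_mixture(b_bins: np.ndarray, pij: PijTable) -> np.ndarray:
    """Pair mass q_k = c_k b_i b_j on adsorbing pairs, renormalized."""
    q = np.array([(1.0 if i == j else 2.0) * b_bins[i] * b_bins[j]
                  for i, j in pij.pairs])
    s = q.sum()
    if s <= 0:
        raise ValueError("weights carry no admissible mass")
    return q / s


def model_distribution_independent(a_i, pij: PijTable) -> np.ndarray:
    """Factorized mixture P(α) = Σ_ij a_i a_j P_ij(α) restricted to the
    adsorbing pairs and renormalized over the admissible mass.

    ``a_i`` is indexed over the grid bins (length grid.n_bins) or over
    ``pij.adsorbing_bins`` (in that order).
    """
    a_i = np.asarray(a_i, float)
    if np.any(a_i < 0):
        raise ValueError("negative weight")
    if a_i.size == pij.grid.n_bins:
        b = a_i
    elif a_i.size == pij.adsorbing_bins.size:
        b = np.zeros(pij.grid.n_bins)
        b[pij.adsorbing_bins] = a_i
    else:
        raise ValueError("weight vector size matches neither the grid nor "
                         "the admitting bins")
    if not np.isclose(b.sum(), 1.0, atol=1e-8):
        raise ValueError("bin weights must sum to 1")
    return pij.hist.T @ _independent_mixture(b, pij)


def chi2_unreduced(hist: AlphaHistogram, model_p: np.ndarray) -> float:
    """Σ_α (N − N_tot P)² / (N_tot P); inf when P = 0 where counts > 0."""
    N = hist.counts
    M = hist.n_tot
    P = np.asarray(model_p, float)
    if P.size != N.size:
        raise ValueError("model/histogram binning mismatch")
    bad = (P <= 0) & (N > 0)
    if np.any(bad):
        return float("inf")
    use = P > 0
    E = M * P[use]
    return float(np.sum((N[use] - E) ** 2 / E))


def _dof(n_bins: int, n_free: int) -> int:
    return max(n_bins - n_free - 1, 1)


def reduced_chi2(hist: AlphaHistogram, model_p: np.ndarray,
                 n_free_params: int = 0, dof: int | None = None) -> float:
    """Reduced χ²: the unreduced sum divided by the degrees of freedom
    (number of α bins − free parameters − 1 by default, floored at 1)."""
    if dof is None:
        dof = _dof(hist.counts.size, n_free_params)
    return chi2_unreduced(hist, model_p) / dof


def chi2_confidence_threshold(dof: int, level: float = 0.05) -> float:
    """Reduced-χ² value above which the fit is rejected at ``level``."""
    return float(stats.chi2.ppf(1.0 - level, dof) / dof)


@dataclass
class FitConfig:
    tol_chi2: float = 1e-3          # |χ² − 1| at convergence (constraint active)
    tol_weights: float = 1e-8
    lambda_max: float = 1e8
    max_bisect: int = 200
    dof: int | None = None          # override the dof convention
    count_free_params: bool = False  # dof = n_bins − n_free − 1 vs n_bins − 1


@dataclass
class FitResult:
    model: str                   # "general" | "independent"
    weights: np.ndarray          # pair weights (general) or bin weights (independent)
    labels: list                 # pij.pairs or admitting bin ids
    lagrange_lambda: float
    normalization_multiplier: float
    chi2: float                  # reduced, at the returned weights
    chi2_unreduced: float
    dof: int
    entropy: float               # −Σ a log(a/m) ≤ 0
    converged: bool
    status: str                  # prior_feasible | constraint_met | constraint_unreachable
    n_iter: int
    model_p: np.ndarray = field(default=None, repr=False)

    def to_json(self, path: str, **provenance) -> None:
        obj = {"model": self.model,
               "weights": self.weights.tolist(),
               "labels": [list(l) if isinstance(l, tuple) else int(l)
                          for l in self.labels],
               "lagrange_lambda": self.lagrange_lambda,
               "normalization_multiplier": self.normalization_multiplier,
               "chi2": self.chi2, "chi2_unreduced": self.chi2_unreduced,
               "dof": self.dof, "entropy": self.entropy,
               "converged": self.converged, "status": self.status,
               "n_iter": self.n_iter, "provenance": provenance}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _softmax(t: np.ndarray) -> np.ndarray:
    t = t - t.max()
    e = np.exp(t)
    return e / e.sum()


def _entropy(a: np.ndarray, m: np.ndarray) -> float:
    use = a > 0
    return float(-np.sum(a[use] * np.log(a[use] / m[use])))


def _solve_lambda(objective, chi2_of, t0: np.ndarray, cfg: FitConfig):
    """Bisection on the χ² multiplier λ with warm-started inner solves.

    ``objective(t, lam)`` returns (f, grad) in softmax coordinates;
    ``chi2_of(t)`` the reduced χ² there.  Returns (t, lam, n_iter, status).
    """

    def inner(lam, t_init):
        res = optimize.minimize(objective, t_init, args=(lam,), jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-14,
                                         "gtol": 1e-10})
        return res.x, res.nit

    n_iter = 0
    chi0 = chi2_of(t0)
    if chi0 <= 1.0:
        return t0, 0.0, 0, "prior_feasible"
    lam_lo, t_lo = 0.0, t0
    lam_hi, t_hi = 1.0, t0
    chi_hi = chi0
    while True:
        t_hi, it = inner(lam_hi, t_hi)
        n_iter += it
        chi_hi = chi2_of(t_hi)
        if chi_hi <= 1.0 or lam_hi >= cfg.lambda_max:
            break
        lam_lo, t_lo = lam_hi, t_hi
        lam_hi *= 8.0
    if chi_hi > 1.0:  # even λ → ∞ cannot reach the constraint
        return t_hi, lam_hi, n_iter, "constraint_unreachable"
    if abs(chi_hi - 1.0) <= cfg.tol_chi2:
        return t_hi, lam_hi, n_iter, "constraint_met"
    t_best, lam_best, chi_best = t_hi, lam_hi, chi_hi
    for _ in range(cfg.max_bisect):
        lam_mid = 0.5 * (lam_lo + lam_hi)
        t_mid, it = inner(lam_mid, t_best)
        n_iter += it
        chi_mid = chi2_of(t_mid)
        if abs(chi_mid - 1.0) < abs(chi_best - 1.0):
            t_best, lam_best, chi_best = t_mid, lam_mid, chi_mid
        if abs(chi_mid - 1.0) <= cfg.tol_chi2:
            return t_mid, lam_mid, n_iter, "constraint_met"
        if chi_mid > 1.0:
            lam_lo = lam_mid
        else:
            lam_hi = lam_mid
    return t_best, lam_best, n_iter, "bisection_exhausted"


def _make_result(model, weights, labels, lam, chi2u, dof, entropy, n_iter,
                 status, model_p, mu=float("nan")) -> FitResult:
    converged = status in ("prior_feasible", "constraint_met")
    return FitResult(model=model, weights=weights, labels=labels,
                     lagrange_lambda=lam, normalization_multiplier=mu,
                     chi2=chi2u / dof, chi2_unreduced=chi2u, dof=dof,
                     entropy=entropy, converged=converged, status=status,
                     n_iter=n_iter, model_p=model_p)


def fit_general(hist: AlphaHistogram, pij: PijTable, prior: PriorWeights,
                config: FitConfig | None = None) -> FitResult:
    """Max-ent fit of the general (correlated-hinge) pair weights a_ij."""
    cfg = config or FitConfig()
    m = prior.pair_bias(pij)
    H = pij.hist                      # (K, n_alpha)
    N = hist.counts
    M = hist.n_tot
    if H.shape[1] != N.size:
        raise ValueError("histogram and P_ij use different α binning")
    K = m.size
    support = H.max(axis=0) > 0          # α bins the mixture can populate
    if np.any((~support) & (N > 0)):
        raise ValueError("histogram has counts in α bins where every "
                         "P_ij is zero: χ² is infinite for any weights")
    Hs = H[:, support]
    Ns = N[support]
    n_free = (K - 1) if cfg.count_free_params else 0
    dof = cfg.dof if cfg.dof is not None else _dof(int(support.sum()), n_free)

    def parts(t):
        a = _softmax(t)
        P = np.maximum(Hs.T @ a, 1e-30)
        return a, P

    def chi2_of(t):
        _, P = parts(t)
        E = M * P
        return float(np.sum((Ns - E) ** 2 / E)) / dof

    def objective(t, lam):
        a, P = parts(t)
        E = M * P
        chi2 = np.sum((Ns - E) ** 2 / E) / dof
        kl = np.sum(a * np.log(np.maximum(a, 1e-300) / m))
        f = kl + lam * chi2
        dP = (M - Ns ** 2 / (M * P ** 2)) / dof      # d(χ²_red)/dP per bin
        grad_a = np.log(np.maximum(a, 1e-300) / m) + 1.0 + lam * (Hs @ dP)
        grad_t = a * (grad_a - np.dot(a, grad_a))
        return f, grad_t

    t0 = np.log(np.maximum(m, 1e-300))
    t, lam, n_iter, status = _solve_lambda(objective, chi2_of, t0, cfg)
    a = _softmax(t) if status != "prior_feasible" else m.copy()
    P = H.T @ a
    chi2u = chi2_unreduced(hist, P)
    # normalization multiplier from the stationarity condition
    # log(a/m) + 1 + λ ∂χ²_red/∂a + μ = 0, averaged over components
    Ps = np.maximum(P[support], 1e-30)
    dP = (M - Ns ** 2 / (M * Ps ** 2)) / dof
    mu = float(-np.mean(np.log(np.maximum(a, 1e-300) / m) + 1.0 + lam * (Hs @ dP)))
    return _make_result("general", a, list(pij.pairs), lam, chi2u, dof,
                        _entropy(a, m), n_iter, status, P, mu)


def fit_independent(hist: AlphaHistogram, pij: PijTable, prior: PriorWeights,
                    config: FitConfig | None = None) -> FitResult:
    """Max-ent fit of the factorized single-hinge weights a_i.

    Entropy term −Σ_i a_i log(a_i/w_i); the mixture uses pair weights
    a_i a_j restricted to the adsorbing pairs and renormalized.
    """
    cfg = config or FitConfig()
    bins = pij.adsorbing_bins
    w = prior.bin_prior(pij)
    B = bins.size
    bin_pos = {b: k for k, b in enumerate(bins)}
    pair_idx = np.array([[bin_pos[i], bin_pos[j]] for i, j in pij.pairs])
    pair_c = np.array([1.0 if i == j else 2.0 for i, j in pij.pairs])
    H = pij.hist
    N = hist.counts
    M = hist.n_tot
    if H.shape[1] != N.size:
        raise ValueError("histogram and P_ij use different α binning")
    support = H.max(axis=0) > 0
    if np.any((~support) & (N > 0)):
        raise ValueError("histogram has counts in α bins where every "
                         "P_ij is zero: χ² is infinite for any weights")
    Hs = H[:, support]
    Ns = N[support]
    n_free = (B - 1) if cfg.count_free_params else 0
    dof = cfg.dof if cfg.dof is not None else _dof(int(support.sum()), n_free)

    def mixture(b):
        q = pair_c * b[pair_idx[:, 0]] * b[pair_idx[:, 1]]
        s = q.sum()
        return q / s

    def chi2_of(t):
        b = _softmax(t)
        P = np.maximum(Hs.T @ mixture(b), 1e-30)
        E = M * P
        return float(np.sum((Ns - E) ** 2 / E)) / dof

    def f_only(t, lam):
        b = _softmax(t)
        P = np.maximum(Hs.T @ mixture(b), 1e-30)
        E = M * P
        chi2 = np.sum((Ns - E) ** 2 / E) / dof
        kl = np.sum(b * np.log(np.maximum(b, 1e-300) / w))
        return kl + lam * chi2

    def objective(t, lam):
        f = f_only(t, lam)
        # forward-difference gradient in the B softmax coordinates
        g = np.empty_like(t)
        h = 1e-7
        for k in range(t.size):
            tk = t.copy()
            tk[k] += h
            g[k] = (f_only(tk, lam) - f) / h
        return f, g

    t0 = np.log(np.maximum(w, 1e-300))
    t, lam, n_iter, status = _solve_lambda(objective, chi2_of, t0, cfg)
    b = _softmax(t) if status != "prior_feasible" else w.copy()
    P = H.T @ mixture(b)
    chi2u = chi2_unreduced(hist, P)
    return _make_result("independent", b, list(map(int, bins)), lam, chi2u,
                        dof, _entropy(b, w), n_iter, status, P)


def two_peak_weights(pij: PijTable) -> np.ndarray:
    """A symmetric two-peak single-hinge weight: equal mass on two bins
    that share a φ bin but sit in well-separated γ bins (the construction
    showing the factorized model must peak at 180°)."""
    grid = pij.grid
    bins = set(map(int, pij.adsorbing_bins))
    best = None
    for p in range(grid.n_phi):
        cands = [g * grid.n_phi + p for g in range(grid.n_gamma)
                 if g * grid.n_phi + p in bins]
        if len(cands) >= 2 and (best is None
                                or cands[-1] - cands[0] > best[1] - best[0]):
            best = (cands[0], cands[-1])
    if best is None:
        raise ValueError("no φ bin admits two γ bins")
    w = np.zeros(grid.n_bins)
    w[best[0]] = w[best[1]] = 0.5
    return w


def independent_peak_check(pij: PijTable, weight_samples=None,
                           n_draws: int = 100, seed: int = 0) -> np.ndarray:
    """Modal α (bin center, degrees) of the factorized model P(α) for a
    battery of single-hinge weight functions.

    Draws ``n_draws`` Dirichlet-random weight vectors over the admitting
    bins, appends the symmetric two-peak construction and any explicitly
    supplied ``weight_samples``, and returns the α-bin center of the
    maximum of P(α) = Σ a_i a_j P_ij(α) for each.  The factorized model
    puts its mode in the bin containing 180° for every weight function —
    the impossibility argument against independent hinges on mica.
    """
    rng = np.random.default_rng(seed)
    bins = pij.adsorbing_bins
    draws = []
    for _ in range(n_draws):
        d = rng.dirichlet(np.ones(bins.size))
        w = np.zeros(pij.grid.n_bins)
        w[bins] = d
        draws.append(w)
    draws.append(two_peak_weights(pij))
    if weight_samples is not None:
        draws.extend(np.asarray(ws, float) for ws in weight_samples)
    centers = pij.alpha_centers
    modes = np.empty(len(draws))
    for k, wv in enumerate(draws):
        P = model_distribution_independent(wv, pij)
        modes[k] = centers[int(np.argmax(P))]
    return modes
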