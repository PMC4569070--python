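"""Maximum-entropy hinge-weight fitting and the mixture models."""

import numpy as np
import pytest

from fibriflex.cg import BinGrid, PijTable
from fibriflex.maxent import (AlphaHistogram, PriorWeights, FitConfig,
                              model_distribution_general,
                              model_distribution_independent,
                              reduced_chi2, chi2_unreduced, fit_general,
                              fit_independent, chi2_confidence_threshold,
                              independent_peak_check, two_peak_weights)
from fibriflex.synthetic import gen_alpha_histogram


@pytest.fixture(scope="module")
def toy_pij():
    """Hand-built two-bin grid with all three pair histograms over 3 α bins."""
    grid = BinGrid(gamma_edges=(60.0, 120.0, 180.0), phi_edges=(-180.0, 180.0))
    pairs = [(0, 0), (0, 1), (1, 1)]
    hist = np.array([[0.7, 0.2, 0.1],
                     [0.1, 0.8, 0.1],
                     [0.1, 0.2, 0.7]])
    return PijTable(alpha_edges=np.array([0.0, 60.0, 120.0, 180.0]),
                    pairs=pairs, hist=hist,
                    counts=np.array([100, 100, 100]), grid=grid)


class TestModelDistributions:
    def test_all_weight_on_one_pair(self, toy_pij):
        P = model_distribution_general([1.0, 0.0, 0.0], toy_pij)
        assert np.allclose(P, toy_pij.hist[0])

    def test_uniform_over_two_pairs_is_mean(self, toy_pij):
        P = model_distribution_general([0.5, 0.5, 0.0], toy_pij)
        assert np.allclose(P, toy_pij.hist[:2].mean(axis=0))

    def test_random_weights_match_dot_product_oracle(self, pij_small):
        rng = np.random.default_rng(0)
        a = rng.dirichlet(np.ones(len(pij_small.pairs)))
        P = model_distribution_general(a, pij_small)
        assert np.allclose(P, pij_small.hist.T @ a)
        assert P.sum() == pytest.approx(1.0)

    def test_weight_on_masked_pair_rejected(self, pij_small):
        masked = [(i, j) for i in range(12) for j in range(i, 12)
                  if not pij_small.is_adsorbing(i, j)][0]
        with pytest.raises(ValueError, match="non-adsorbing"):
            model_distribution_general({masked: 1.0}, pij_small)

    def test_independent_delta_weight_gives_diagonal(self, toy_pij):
        a = np.array([1.0, 0.0])
        P = model_distribution_independent(a, toy_pij)
        assert np.allclose(P, toy_pij.hist[0])

    def test_independent_half_half_binomial_expansion(self, toy_pij):
        P = model_distribution_independent(np.array([0.5, 0.5]), toy_pij)
        expected = 0.25 * toy_pij.hist[0] + 0.5 * toy_pij.hist[1] \
            + 0.25 * toy_pij.hist[2]
        assert np.allclose(P, expected)

    def test_independent_consistent_with_general(self, pij_small):
        rng = np.random.default_rng(1)
        bins = pij_small.adsorbing_bins
        b = np.zeros(12)
        b[bins] = rng.dirichlet(np.ones(bins.size))
        P_ind = model_distribution_independent(b, pij_small)
        q = np.array([(1 if i == j else 2) * b[i] * b[j]
                      for i, j in pij_small.pairs])
        P_gen = model_distribution_general(q / q.sum(), pij_small)
        assert np.allclose(P_ind, P_gen)


class TestReducedChi2:
    def test_exact_match_is_zero(self):
        hist = AlphaHistogram(edges=[0, 90, 180], counts=[30, 70])
        assert chi2_unreduced(hist, np.array([0.3, 0.7])) == pytest.approx(0.0)

    def test_one_bin_toy_hand_arithmetic(self):
        hist = AlphaHistogram(edges=[0, 180], counts=[10])
        # (10 − 5)² / 5 = 5 with dof = 1
        assert reduced_chi2(hist, np.array([0.5]), dof=1) == pytest.approx(5.0)

    def test_doubling_counts_doubles_unreduced_sum(self):
        P = np.array([0.4, 0.6])
        h1 = AlphaHistogram(edges=[0, 90, 180], counts=[50, 50])
        h2 = AlphaHistogram(edges=[0, 90, 180], counts=[100, 100])
        assert chi2_unreduced(h2, P) == pytest.approx(2 * chi2_unreduced(h1, P))

    def test_zero_model_mass_with_counts_is_infinite(self):
        hist = AlphaHistogram(edges=[0, 90, 180], counts=[10, 10])
        assert chi2_unreduced(hist, np.array([1.0, 0.0])) == np.inf


class TestFitGeneral:
    def test_prior_consistent_data_returns_prior(self, pij_small):
        prior = PriorWeights.uniform(pij_small)
        m = prior.pair_bias(pij_small)
        P = pij_small.hist.T @ m
        counts = np.round(P * 100000)
        hist = AlphaHistogram(edges=pij_small.alpha_edges, counts=counts)
        res = fit_general(hist, pij_small, prior)
        assert res.status == "prior_feasible"
        assert res.converged
        assert np.allclose(res.weights, m)
        assert res.entropy == pytest.approx(0.0, abs=1e-12)

    def test_chi2_driven_to_one_on_non_prior_data(self, pij_small):
        rng = np.random.default_rng(5)
        K = len(pij_small.pairs)
        offdiag = [k for k, (i, j) in enumerate(pij_small.pairs) if i != j]
        true_w = np.zeros(K)
        pick = rng.choice(offdiag, 6, replace=False)
        true_w[pick] = rng.dirichlet(np.ones(6))
        hist = gen_alpha_histogram(true_w, pij_small, n_tot=1000, seed=11,
                                   model="general")
        res = fit_general(hist, pij_small, PriorWeights.uniform(pij_small))
        assert res.converged
        assert res.chi2 == pytest.approx(1.0, abs=1e-3)
        assert res.weights.sum() == pytest.approx(1.0)
        assert np.all(res.weights >= 0)

    def test_two_pair_toy_matches_grid_search(self, toy_pij):
        """One free parameter: compare against a brute-force scan of the
        entropy under the χ² ≤ 1 constraint."""
        grid = toy_pij.grid
        pij2 = PijTable(alpha_edges=toy_pij.alpha_edges,
                        pairs=[(0, 0), (1, 1)],
                        hist=toy_pij.hist[[0, 2]],
                        counts=np.array([100, 100]), grid=grid)
        prior = PriorWeights(w=np.array([0.5, 0.5]))
        hist = AlphaHistogram(edges=toy_pij.alpha_edges,
                              counts=[100.0, 200.0, 700.0])
        cfg = FitConfig(dof=2)
        res = fit_general(hist, pij2, prior, cfg)
        m = prior.pair_bias(pij2)
        best, best_s = None, -np.inf
        for p in np.linspace(1e-6, 1 - 1e-6, 20001):
            a = np.array([p, 1 - p])
            chi2 = chi2_unreduced(hist, pij2.hist.T @ a) / 2
            if chi2 <= 1.0 + 1e-3:
                s = -np.sum(a * np.log(a / m))
                if s > best_s:
                    best, best_s = p, s
        assert best is not None
        assert res.weights[0] == pytest.approx(best, abs=1e-4)

    def test_bit_reproducible(self, pij_small):
        hist = gen_alpha_histogram(
            np.full(len(pij_small.pairs), 1.0 / len(pij_small.pairs)),
            pij_small, n_tot=500, seed=3, model="general")
        prior = PriorWeights.from_occupancy(pij_small)
        r1 = fit_general(hist, pij_small, prior)
        r2 = fit_general(hist, pij_small, prior)
        assert np.array_equal(r1.weights, r2.weights)
        assert r1.chi2 == r2.chi2


class TestFitIndependent:
    def test_factorized_data_recovered(self, pij_small):
        rng = np.random.default_rng(8)
        bins = pij_small.adsorbing_bins
        b = np.zeros(12)
        b[bins] = rng.dirichlet(np.full(bins.size, 2.0))
        hist = gen_alpha_histogram(b, pij_small, n_tot=1000, seed=21,
                                   model="independent")
        res = fit_independent(hist, pij_small, PriorWeights.uniform(pij_small))
        assert res.converged
        assert res.chi2 <= 1.0 + 1e-3

    def test_single_bin_degenerate_grid(self):
        grid = BinGrid(gamma_edges=(60.0, 180.0), phi_edges=(-180.0, 180.0))
        pij = PijTable(alpha_edges=np.array([0.0, 90.0, 180.0]),
                       pairs=[(0, 0)], hist=np.array([[0.4, 0.6]]),
                       counts=np.array([50]), grid=grid)
        hist = AlphaHistogram(edges=[0.0, 90.0, 180.0], counts=[50, 50])
        res = fit_independent(hist, pij, PriorWeights(w=np.array([1.0])))
        assert res.weights.tolist() == [1.0]
        expected = chi2_unreduced(hist, pij.hist[0])
        assert res.chi2_unreduced == pytest.approx(expected)

    def test_anti_diagonal_weights_not_fittable(self, pij_small):
        """Data from strongly correlated (anti-diagonal) pair weights defeat
        the factorized model: its best χ² stays above the 5% confidence
        threshold while the general model reaches χ² = 1."""
        rng = np.random.default_rng(2)
        K = len(pij_small.pairs)
        gsep = [k for k, (i, j) in enumerate(pij_small.pairs)
                if abs(i // 4 - j // 4) == 2]
        true_w = np.zeros(K)
        true_w[gsep] = rng.dirichlet(np.ones(len(gsep)))
        hist = gen_alpha_histogram(true_w, pij_small, n_tot=4000, seed=13,
                                   model="general")
        prior = PriorWeights.uniform(pij_small)
        cfg = FitConfig(dof=25)
        res_ind = fit_independent(hist, pij_small, prior, cfg)
        res_gen = fit_general(hist, pij_small, prior, cfg)
        thresh = chi2_confidence_threshold(25, 0.05)
        assert res_ind.chi2 > thresh
        assert res_gen.chi2 <= 1.0 + 1e-3
        assert res_gen.chi2 <= res_ind.chi2


class TestInvariants:
    def test_entropy_nonpositive_zero_iff_prior(self, pij_small):
        prior = PriorWeights.uniform(pij_small)
        hist = gen_alpha_histogram(
            np.full(len(pij_small.pairs), 1.0 / len(pij_small.pairs)),
            pij_small, n_tot=2000, seed=4, model="general")
        res = fit_general(hist, pij_small, prior)
        assert res.entropy <= 1e-12
        if res.status != "prior_feasible":
            assert res.entropy < 0

    def test_prior_rescaling_leaves_fit_unchanged(self, pij_small):
        """m enters only through ratios: scaling all prior weights by a
        constant changes nothing."""
        rng = np.random.default_rng(6)
        K = len(pij_small.pairs)
        true_w = rng.dirichlet(np.ones(K))
        hist = gen_alpha_histogram(true_w, pij_small, n_tot=800, seed=9,
                                   model="general")
        w = np.zeros(12)
        w[pij_small.adsorbing_bins] = rng.dirichlet(
            np.ones(pij_small.adsorbing_bins.size))
        r1 = fit_general(hist, pij_small, PriorWeights(w=w))
        r2 = fit_general(hist, pij_small, PriorWeights(w=7.3 * w))
        assert np.allclose(r1.weights, r2.weights, atol=1e-9)

    def test_nested_models_chi2_ordering(self, pij_small):
        """The factorized family is inside the general one, so the general
        fit never does worse (same dof convention)."""
        cfg = FitConfig(dof=25)
        prior = PriorWeights.uniform(pij_small)
        rng = np.random.default_rng(10)
        for seed in (1, 2, 3):
            true_w = rng.dirichlet(np.ones(len(pij_small.pairs)))
            hist = gen_alpha_histogram(true_w, pij_small, n_tot=1500,
                                       seed=seed, model="general")
            rg = fit_general(hist, pij_small, prior, cfg)
            ri = fit_independent(hist, pij_small, prior, cfg)
            # both may sit at the χ² = 1 constraint within solver tolerance
            assert rg.chi2 <= ri.chi2 + 2e-3


class TestIndependentPeak:
    def test_delta_weight_on_unbent_bin_modes_at_180(self, pij_small):
        grid = pij_small.grid
        centers = pij_small.alpha_centers
        last = centers[-1]
        for b in pij_small.adsorbing_bins:
            if not pij_small.is_adsorbing(b, b):
                continue  # a lone hinge bin whose diagonal pair cannot adsorb
            if b // grid.n_phi == grid.n_gamma - 1:  # unbent γ bin
                w = np.zeros(12)
                w[b] = 1.0
                P = model_distribution_independent(w, pij_small)
                assert centers[np.argmax(P)] == last

    def test_two_peak_construction_modes_at_180(self, pij_small):
        w = two_peak_weights(pij_small)
        assert np.count_nonzero(w) == 2
        P = model_distribution_independent(w, pij_small)
        centers = pij_small.alpha_centers
        assert 175.0 <= centers[np.argmax(P)] <= 180.0

    def test_peak_check_reports_one_mode_per_draw(self, pij_small):
        modes = independent_peak_check(pij_small, n_draws=20, seed=0)
        assert modes.shape == (21,)  # 20 draws + the two-peak construction
        assert np.all((modes >= 0) & (modes <= 180))


class TestHistogramIO:
    def test_csv_round_trip(self, tmp_path):
        h = AlphaHistogram(edges=np.arange(0, 181, 30.0),
                           counts=[1.0, 4, 9, 16, 9, 4])
        p = str(tmp_path / "h.csv")
        h.to_csv(p)
        back = AlphaHistogram.from_csv(p)
        assert np.allclose(back.edges, h.edges)
        assert np.allclose(back.counts, h.counts)
        assert back.n_tot == 43

    def test_fit_result_json(self, tmp_path, pij_small):
        prior = PriorWeights.uniform(pij_small)
        hist = gen_alpha_histogram(
            np.full(len(pij_small.pairs), 1.0 / len(pij_small.pairs)),
            pij_small, n_tot=300, seed=2, model="general")
        res = fit_general(hist, pij_small, prior)
        path = str(tmp_path / "fit.json")
        res.to_json(path, seed=2, grid="default")
        import json
        obj = json.load(open(path))
        assert obj["model"] == "general"
        assert obj["provenance"]["seed"] == 2
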