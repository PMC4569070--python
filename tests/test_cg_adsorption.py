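"""Rod-and-sphere adsorption model: embedding, sampling, binning."""

import numpy as np
import pytest

from fibriflex.cg import (CGGeometry, BinGrid, build_geometry,
                          place_conformation, measure_angles, is_adsorbed,
                          measure_alpha, mc_generate, bin_pij,
                          DEFAULT_GEOMETRY, DegenerateProjectionError)


class TestBuildGeometry:
    @staticmethod
    def _blob(center, spread=1.0):
        # zero-mean tetrahedron around the center: centroid is exact
        tet = np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
        return np.asarray(center, float) + spread * tet

    def test_labelled_points_give_hand_set_distances(self):
        groups = {"E": self._blob([0.0, 0, 0]),
                  "hinge1": self._blob([7.0, 0, 0]),
                  "D1": self._blob([7.0, 9.0, 0])}
        g = build_geometry(groups, h_max=3.0)
        assert g.rod_half_length == pytest.approx(7.0)
        assert g.arm_length == pytest.approx(9.0)

    def test_symmetric_dimer_averages_equal_halves(self):
        groups = {"E": self._blob([0.0, 0, 0]),
                  "hinge1": self._blob([-8.0, 0, 0]),
                  "D1": self._blob([-16.0, 0, 0]),
                  "hinge2": self._blob([8.0, 0, 0]),
                  "D2": self._blob([16.0, 0, 0])}
        g = build_geometry(groups, h_max=3.0)
        assert g.rod_half_length == pytest.approx(8.0)
        assert g.arm_length == pytest.approx(8.0)

    def test_sphere_radius_is_radius_of_gyration(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(size=(200, 3)) * 2.0
        groups = {"E": cloud, "hinge1": self._blob([8.0, 0, 0]),
                  "D1": cloud + np.array([16.0, 0, 0])}
        g = build_geometry(groups)
        c = cloud - cloud.mean(axis=0)
        rg = np.sqrt((c ** 2).sum(axis=1).mean())
        assert g.r_e == pytest.approx(rg)
        assert g.h_max == pytest.approx(1.1 * g.r_d)

    def test_missing_group_raises(self):
        with pytest.raises(KeyError, match="D1"):
            build_geometry({"E": np.zeros((1, 3)), "hinge1": np.ones((1, 3))})


class TestPlaceAndMeasure:
    def test_fully_extended_is_collinear(self):
        c = place_conformation(180.0, 35.0, 180.0, -120.0)
        pts = np.stack([c.d1_center, c.hinge1, c.e_center, c.hinge2, c.d2_center])
        d = pts - pts[0]
        cross = np.cross(d[1:], d[-1])
        assert np.linalg.norm(cross) == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn_points_down_in_reference_plane(self):
        # φ = 0 is the x0 reference (straight toward the surface)
        c = place_conformation(90.0, 0.0, 160.0, 10.0)
        arm = c.d1_center - c.hinge1
        assert arm[0] == pytest.approx(0.0, abs=1e-12)
        assert arm[1] == pytest.approx(0.0, abs=1e-12)
        assert arm[2] == pytest.approx(-DEFAULT_GEOMETRY.arm_length)

    def test_round_trip_identity_over_random_draws(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(1000):
            g1, g2 = rng.uniform(0.5, 179.5, 2)
            p1, p2 = rng.uniform(-179.5, 180.0, 2)
            c = place_conformation(g1, p1, g2, p2)
            m = measure_angles(c)
            worst = max(worst, abs(m[0] - g1), abs(m[1] - p1),
                        abs(m[2] - g2), abs(m[3] - p2))
        assert worst < 1e-6

    def test_rod_length_invariants(self):
        c = place_conformation(120.0, 40.0, 100.0, -30.0)
        g = DEFAULT_GEOMETRY
        assert np.linalg.norm(c.hinge1 - c.e_center) == pytest.approx(g.rod_half_length)
        assert np.linalg.norm(c.hinge2 - c.e_center) == pytest.approx(g.rod_half_length)
        assert np.linalg.norm(c.d1_center - c.hinge1) == pytest.approx(g.arm_length)
        assert np.linalg.norm(c.d2_center - c.hinge2) == pytest.approx(g.arm_length)

    def test_out_of_range_angles_rejected(self):
        with pytest.raises(ValueError):
            place_conformation(190.0, 0.0, 90.0, 0.0)
        with pytest.raises(ValueError):
            place_conformation(90.0, -181.0, 90.0, 0.0)

    def test_mirror_symmetry_preserves_alpha(self):
        """Reflection through the vertical plane of the rod flips both
        torsions' signs and leaves α unchanged."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            g1, g2 = rng.uniform(30, 175, 2)
            p1, p2 = rng.uniform(-179, 180, 2)
            a = measure_alpha(place_conformation(g1, p1, g2, p2))
            b = measure_alpha(place_conformation(g1, -p1, g2, -p2))
            assert a == pytest.approx(b, abs=1e-9)


class TestIsAdsorbed:
    def test_all_regions_in_contact_true(self, mc_samples_small):
        # an MC-accepted conformation has all three regions in exact contact
        s = mc_samples_small
        c = place_conformation(s.gamma1[0], s.phi1[0], s.gamma2[0], s.phi2[0],
                               theta=float(s.theta[0]))
        g = DEFAULT_GEOMETRY
        assert c.e_center[2] == pytest.approx(g.r_e)
        assert c.d1_center[2] == pytest.approx(g.r_d, abs=1e-9)
        assert is_adsorbed(c, g)

    def test_far_d_region_false(self):
        c = place_conformation(90.0, 180.0, 90.0, 180.0)  # arms point up
        g = DEFAULT_GEOMETRY
        assert c.d1_center[2] - g.r_d > g.h_max
        assert not is_adsorbed(c, g)

    def test_hinge_below_surface_false(self):
        c = place_conformation(90.0, 0.0, 90.0, 0.0)
        c.hinge1[2] = -0.1
        assert not is_adsorbed(c, DEFAULT_GEOMETRY)


class TestMeasureAlpha:
    def test_fully_extended_projects_to_180(self):
        assert measure_alpha(place_conformation(180.0, 0.0, 180.0, 0.0)) == \
            pytest.approx(180.0)

    def test_symmetric_hinges_project_to_180(self):
        assert measure_alpha(place_conformation(120.0, 55.0, 120.0, 55.0)) == \
            pytest.approx(180.0)

    def test_right_angle_construction(self):
        c = place_conformation(160.0, 20.0, 160.0, -60.0)
        # oracle: independent 2-D angle computation on the projections
        v1 = (c.d1_center - c.e_center)[:2]
        v2 = (c.d2_center - c.e_center)[:2]
        expected = np.degrees(np.arccos(
            np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)))
        assert measure_alpha(c) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_projection_raises(self):
        c = place_conformation(100.0, 0.0, 100.0, 0.0)
        c.d1_center = c.e_center.copy()
        with pytest.raises(DegenerateProjectionError):
            measure_alpha(c)


class TestMCGenerate:
    def test_zero_samples_empty(self):
        s = mc_generate(0, seed=1)
        assert len(s) == 0

    def test_deterministic_under_seed(self):
        a = mc_generate(2000, seed=5)
        b = mc_generate(2000, seed=5)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.bin1, b.bin1)

    def test_alpha_and_angle_ranges(self, mc_samples_small):
        s = mc_samples_small
        assert np.all((s.alpha >= 0) & (s.alpha <= 180))
        assert np.all((s.gamma1 >= 60) & (s.gamma1 <= 180))
        assert np.all((s.phi2 > -180) & (s.phi2 <= 180))

    def test_samples_satisfy_contact_and_adsorption(self, mc_samples_small):
        """Re-embedding sampled angles at the sampled tilt reproduces
        surface contact of E and both D spheres, hinges above."""
        s = mc_samples_small
        g = DEFAULT_GEOMETRY
        idx = np.random.default_rng(0).choice(len(s), 200, replace=False)
        for k in idx:
            c = place_conformation(s.gamma1[k], s.phi1[k], s.gamma2[k],
                                   s.phi2[k], theta=float(s.theta[k]))
            assert c.d1_center[2] == pytest.approx(g.r_d, abs=1e-6)
            assert c.d2_center[2] == pytest.approx(g.r_d, abs=1e-6)
            assert is_adsorbed(c, g)
            assert measure_alpha(c) == pytest.approx(s.alpha[k], abs=1e-6)

    def test_bin_occupancy_uniform_in_bin_stratification(self):
        """With per-bin stratification the per-hinge bin occupancy is
        uniform over admitting bins within multinomial error."""
        s = mc_generate(100_000, seed=3, stratify="bins")
        occ = np.bincount(np.r_[s.bin1, s.bin2], minlength=s.grid.n_bins)
        occ = occ[occ > 0]
        expect = occ.mean()
        sigma = np.sqrt(expect)
        assert np.all(np.abs(occ - expect) < 3 * sigma + 3)

    def test_pair_stratification_equalizes_pair_counts(self, mc_samples_small):
        s = mc_samples_small
        pairs, counts = np.unique(np.stack([s.bin1, s.bin2]), axis=1,
                                  return_counts=True)
        assert counts.max() - counts.min() <= 1


class TestBinPij:
    def test_single_pair_histogram_sums_to_one(self, mc_samples_small):
        s = mc_samples_small
        pij = bin_pij(s)
        assert np.allclose(pij.hist.sum(axis=1), 1.0)

    def test_symmetry_of_pair_lookup(self, mc_samples_small):
        pij = bin_pij(mc_samples_small)
        i, j = pij.pairs[1]
        assert np.array_equal(pij.p_alpha(i, j), pij.p_alpha(j, i))

    def test_adsorbing_pair_set_symmetric(self, mc_samples_small):
        pij = bin_pij(mc_samples_small)
        for i, j in pij.pairs:
            assert pij.is_adsorbing(j, i)

    def test_masked_pair_raises(self, mc_samples_small):
        pij = bin_pij(mc_samples_small)
        masked = [(i, j) for i in range(12) for j in range(i, 12)
                  if not pij.is_adsorbing(i, j)]
        assert masked, "expected some non-adsorbing pairs in this geometry"
        with pytest.raises(KeyError):
            pij.p_alpha(*masked[0])

    def test_json_round_trip(self, tmp_path, mc_samples_small):
        pij = bin_pij(mc_samples_small)
        path = str(tmp_path / "pij.json")
        pij.to_json(path)
        from fibriflex.cg import PijTable
        back = PijTable.from_json(path)
        assert back.pairs == pij.pairs
        assert np.allclose(back.hist, pij.hist)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            bin_pij(mc_generate(0, seed=1))


class TestBinGrid:
    def test_default_grid_has_twelve_bins(self):
        g = BinGrid()
        assert g.n_bins == 12
        assert g.gamma_edges == (60.0, 100.0, 140.0, 180.0)

    def test_right_closed_membership(self):
        g = BinGrid()
        # "60 < γ ≤ 100" style intervals
        assert g.bin_index(100.0, -135.0) == g.bin_index(80.0, -135.0)
        assert g.bin_index(100.0001, -135.0) != g.bin_index(100.0, -135.0)

    def test_out_of_range_is_minus_one(self):
        g = BinGrid()
        assert g.bin_index(30.0, 0.0) == -1

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            BinGrid(gamma_edges=(60.0, 60.0, 180.0))
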