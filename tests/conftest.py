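import numpy as np
import pytest

from fibriflex.cg import mc_generate, bin_pij
from fibriflex.trajectory import Trajectory


@pytest.fixture(scope="session")
def pij_small():
    """A modest Monte-Carlo P_ij(α) table shared across fitting tests."""
    samples = mc_generate(120_000, seed=42)
    return bin_pij(samples)


@pytest.fixture(scope="session")
def mc_samples_small():
    return mc_generate(60_000, seed=7)


def _scatter(rng, center, n, spread):
    return center + rng.normal(0.0, spread, (n, 3))


@pytest.fixture(scope="session")
def crystal_like_protomer():
    """Synthetic stand-in for an elongated fibrinogen protomer crystal.

    A Cα-only model (chains A = Aα, B = Bβ, C = γ, crystal residue
    numbering) whose E, hinge and D regions sit at the coarse positions of
    the published crystal shape: E-to-hinge ≈ 8 nm along the coiled coil,
    hinge-to-D ≈ 8.5 nm, with the slight bend of the elongated molecule.
    It exercises the published atom-group definitions on realistic
    numbering; it is NOT the crystal structure itself.
    """
    rng = np.random.default_rng(2026)
    e_c = np.array([0.0, 0.0, 0.0])
    h_c = np.array([80.0, 0.0, 0.0])            # Å
    bend = np.radians(180.0 - 160.0)             # slight crystal bend
    d_c = h_c + 85.0 * np.array([np.cos(bend), np.sin(bend), 0.0])

    chains, resids, coords = [], [], []

    def add(chain, lo, hi, center, spread):
        n = hi - lo + 1
        pts = _scatter(rng, center, n, spread)
        pts -= pts.mean(axis=0) - center        # centroid exactly at center
        chains.extend([chain] * n)
        resids.extend(range(lo, hi + 1))
        coords.append(pts)

    # E region: α50–58, β82–90, γ23–31
    add("A", 50, 58, e_c, 8.0)
    add("B", 82, 90, e_c, 8.0)
    add("C", 23, 31, e_c, 8.0)
    # hinge region: α99–110, β130–155, γ70–100
    add("A", 99, 110, h_c, 8.0)
    add("B", 130, 155, h_c, 8.0)
    add("C", 70, 100, h_c, 8.0)
    # D region: β200–458, γ140–394
    add("B", 200, 458, d_c, 25.0)
    add("C", 140, 394, d_c, 25.0)

    return Trajectory(coords=np.concatenate(coords)[None],
                      chain_ids=np.array(chains, object),
                      resids=np.array(resids),
                      atom_names=np.array(["CA"] * len(chains), object))
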