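import numpy as np
import pytest

import atmkit as ak


@pytest.fixture
def harmonic_system():
    """Asymmetric host-guest with closed-form ΔΔG = -(3/2) ln 4 at kT=1."""
    return ak.make_harmonic_host_guest(k_site=4.0, k_bulk=1.0, k_site_b=1.0,
                                       k_bulk_b=1.0, kT=1.0)


@pytest.fixture
def symmetric_system():
    """Identical ligands: ΔΔG is exactly zero."""
    return ak.make_harmonic_host_guest(k_site=4.0, k_bulk=1.0, k_site_b=4.0,
                                       k_bulk_b=1.0, kT=1.0)


@pytest.fixture
def lj_system():
    return ak.make_lj_ligand_system(n_beads_a=4, n_beads_b=2, seed=3)


@pytest.fixture
def surrogate():
    return ak.SurrogateParams.create(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def finite_difference_gradient(fn, coords, h=1e-5):
    """Central-difference gradient of a scalar coordinate function."""
    coords = np.asarray(coords, dtype=float)
    grad = np.zeros_like(coords)
    it = np.nditer(coords, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = coords.copy()
        xp[idx] += h
        xm = coords.copy()
        xm[idx] -= h
        grad[idx] = (fn(xp) - fn(xm)) / (2.0 * h)
    return grad
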