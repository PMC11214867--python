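"""ATM core: swap transform, perturbation energy, soft-core, bias, schedule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import atmkit as ak
from atmkit.alchemy import (alchemical_bias_derivative, softcore_derivative,
                            total_alchemical_energy)
from atmkit.errors import InvalidParameterError

from conftest import finite_difference_gradient

COORD = st.floats(min_value=-3.0, max_value=3.0, allow_nan=False)


class TestSwapTransform:
    def test_involution(self, harmonic_system, rng):
        x = harmonic_system.coordinates + rng.normal(0, 0.8, (2, 3))
        back = ak.swap_transform(
            ak.swap_transform(x, harmonic_system), harmonic_system)
        np.testing.assert_allclose(back, x, atol=1e-12)

    def test_site_particle_lands_on_bulk_center(self, harmonic_system):
        x = harmonic_system.coordinates.copy()
        swapped = ak.swap_transform(x, harmonic_system)
        np.testing.assert_array_equal(swapped[0],
                                      harmonic_system.bulk_center)
        np.testing.assert_array_equal(swapped[1],
                                      harmonic_system.site_center)

    def test_environment_untouched(self, lj_system, rng):
        x = lj_system.coordinates + rng.normal(0, 0.05,
                                               lj_system.coordinates.shape)
        swapped = ak.swap_transform(x, lj_system)
        env = np.asarray(lj_system.environment_indices)
        np.testing.assert_array_equal(swapped[env], x[env])

    def test_swapped_state_transfers_back(self, lj_system):
        once = ak.swap_transform(lj_system.coordinates, lj_system)
        lig_a = np.asarray(lj_system.ligand_a)
        # ligand A moved by +displacement toward the bulk
        np.testing.assert_allclose(
            once[lig_a] - lj_system.coordinates[lig_a],
            np.broadcast_to(lj_system.displacement, (len(lig_a), 3)))

    def test_overlapping_groups_rejected(self, harmonic_system):
        bad = ak.ToySystem(
            coordinates=harmonic_system.coordinates,
            potential_terms=harmonic_system.potential_terms,
            ligand_a=(0,), ligand_b=(1,),
            site_center=harmonic_system.site_center,
            bulk_center=harmonic_system.bulk_center,
            temperature=harmonic_system.temperature)
        bad.ligand_b = (0,)  # bypass constructor validation
        with pytest.raises(InvalidParameterError):
            ak.swap_transform(harmonic_system.coordinates, bad)


class TestPerturbationEnergy:
    @settings(derandomize=True, max_examples=30)
    @given(st.lists(COORD, min_size=6, max_size=6))
    def test_antisymmetry_under_swap(self, flat):
        system = ak.make_harmonic_host_guest(2.0, 1.0, 3.0, 0.5, kT=1.0)
        x = system.coordinates + np.asarray(flat).reshape(2, 3)
        u = ak.perturbation_energy(x, system)
        u_swapped = ak.perturbation_energy(
            ak.swap_transform(x, system), system)
        assert u_swapped == pytest.approx(-u, abs=1e-9)

    def test_symmetric_configuration_gives_zero(self):
        system = ak.make_harmonic_host_guest(2.0, 2.0, 2.0, 2.0, kT=1.0)
        assert ak.perturbation_energy(system.coordinates, system) == 0.0

    def test_hand_worked_value(self):
        """A displaced 1 A from the site with k 2 -> 1: u = 0.5 - 1.0."""
        system = ak.make_harmonic_host_guest(2.0, 1.0, 2.0, 1.0, kT=1.0)
        x = system.coordinates.copy()
        x[0] += np.array([1.0, 0.0, 0.0])
        e0 = ak.hybrid_energy(x, system, "mm").energy
        e1 = ak.hybrid_energy(ak.swap_transform(x, system), system,
                              "mm").energy
        assert e0 == pytest.approx(1.0)
        assert e1 == pytest.approx(0.5)
        assert ak.perturbation_energy(x, system) == pytest.approx(-0.5)


class TestSoftCore:
    sc = ak.SoftCoreParams(umax=200.0, uc=100.0, a=1 / 16)

    def test_identity_branch(self):
        for u in (-50.0, 0.0, 99.9, 100.0):
            assert ak.softcore(u, self.sc) == u

    def test_joint_is_c1(self):
        eps = 1e-6
        lo = (ak.softcore(100.0, self.sc) - ak.softcore(100.0 - eps,
                                                        self.sc)) / eps
        hi = (ak.softcore(100.0 + eps, self.sc) - ak.softcore(100.0,
                                                              self.sc)) / eps
        assert lo == pytest.approx(1.0, abs=1e-4)
        assert hi == pytest.approx(1.0, abs=1e-4)

    def test_large_u_approaches_umax(self):
        assert ak.softcore(1e6, self.sc) == pytest.approx(200.0, abs=1e-3)
        assert ak.softcore(1e12, self.sc) <= 200.0

    def test_strictly_increasing_and_bounded(self):
        u = np.linspace(-150.0, 5000.0, 4001)
        out = ak.softcore(u, self.sc)
        # monotone up to float64 roundoff at the umax saturation plateau
        assert np.all(np.diff(out) >= -1e-12)
        below = u < 400.0
        assert np.all(np.diff(out[below]) > 0)
        assert np.all(out <= 200.0)

    def test_derivative_matches_finite_differences(self):
        for u in (-20.0, 80.0, 110.0, 150.0, 400.0):
            h = 1e-5
            fd = (ak.softcore(u + h, self.sc)
                  - ak.softcore(u - h, self.sc)) / (2 * h)
            assert softcore_derivative(u, self.sc) == pytest.approx(
                fd, rel=1e-5, abs=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            ak.SoftCoreParams(umax=50.0, uc=100.0)
        with pytest.raises(InvalidParameterError):
            ak.SoftCoreParams(a=0.0)


class TestAlchemicalBias:
    def test_linear_reduction(self):
        state = ak.AlchemicalState(lam=0.5, lam1=0.5, lam2=0.5, w0=0.0)
        assert ak.alchemical_bias(3.0, state) == pytest.approx(1.5)
        u = np.linspace(-400, 400, 101)
        state2 = ak.AlchemicalState(lam=0.2, lam1=0.2, lam2=0.2, w0=1.0)
        np.testing.assert_allclose(ak.alchemical_bias(u, state2),
                                   0.2 * u + 1.0, atol=1e-12)

    def test_softplus_value_at_u0(self):
        # slope-interpolating form: W(0) = (lam2-lam1)/alpha * ln 2
        state = ak.AlchemicalState(lam=0.1, lam1=0.2, lam2=0.1, alpha=0.1,
                                   u0=0.0, w0=0.0)
        assert ak.alchemical_bias(0.0, state) == pytest.approx(-np.log(2.0))

    def test_asymptotes(self):
        state = ak.AlchemicalState(lam=0.25, lam1=0.4, lam2=0.1, alpha=0.1,
                                   u0=50.0, w0=0.7)
        big = 1e5
        assert ak.alchemical_bias(big, state) == pytest.approx(
            0.1 * big + 0.7, rel=1e-10)
        small = -1e5
        # slope lam1 branch for very favorable u: W -> lam1 u - (lam1-lam2) u0 + w0
        expected = 0.4 * small - (0.4 - 0.1) * 50.0 + 0.7
        assert ak.alchemical_bias(small, state) == pytest.approx(
            expected, rel=1e-9)

    def test_monotone_when_slopes_nonnegative(self):
        state = ak.AlchemicalState(lam=0.25, lam1=0.45, lam2=0.05, alpha=0.3,
                                   u0=20.0)
        u = np.linspace(-500, 500, 2001)
        w = ak.alchemical_bias(u, state)
        assert np.all(np.diff(w) >= 0)

    def test_derivative_matches_finite_differences(self):
        state = ak.AlchemicalState(lam=0.25, lam1=0.4, lam2=0.1, alpha=0.2,
                                   u0=10.0)
        for u in (-30.0, 0.0, 10.0, 80.0):
            h = 1e-6
            fd = (ak.alchemical_bias(u + h, state)
                  - ak.alchemical_bias(u - h, state)) / (2 * h)
            assert alchemical_bias_derivative(u, state) == pytest.approx(
                fd, rel=1e-6)

    def test_alpha_zero_with_distinct_slopes_rejected(self):
        with pytest.raises(InvalidParameterError):
            ak.AlchemicalState(lam=0.2, lam1=0.3, lam2=0.1, alpha=0.0)
        # alpha = 0 is fine for linear coupling
        ak.AlchemicalState(lam=0.2, lam1=0.2, lam2=0.2, alpha=0.0)


class TestTotalAlchemicalEnergy:
    def test_reduces_to_plain_energy_at_lambda_zero(self, lj_system,
                                                    surrogate, rng):
        state = ak.AlchemicalState(lam=0.0, lam1=0.0, lam2=0.0, w0=0.0)
        x = lj_system.coordinates + rng.normal(
            0, 0.05, lj_system.coordinates.shape)
        for mode in ("mm", "hybrid"):
            res = total_alchemical_energy(x, lj_system, state, mode,
                                          surrogate)
            plain = ak.hybrid_energy(x, lj_system, mode, surrogate)
            assert res.energy == pytest.approx(plain.energy, abs=1e-12)
            np.testing.assert_allclose(res.gradient, plain.gradient,
                                       atol=1e-12)

    @pytest.mark.parametrize("mode", ["mm", "hybrid"])
    def test_gradient_matches_finite_differences(self, lj_system, surrogate,
                                                 rng, mode):
        state = ak.AlchemicalState(lam=0.3, lam1=0.3, lam2=0.18, alpha=0.1,
                                   u0=10.0)
        x = lj_system.coordinates + rng.normal(
            0, 0.05, lj_system.coordinates.shape)
        res = total_alchemical_energy(x, lj_system, state, mode, surrogate)
        fd = finite_difference_gradient(
            lambda y: total_alchemical_energy(y, lj_system, state, mode,
                                              surrogate).energy, x)
        scale = max(np.max(np.abs(fd)), 1.0)
        assert np.max(np.abs(res.gradient - fd)) / scale < 1e-5

    def test_midpoint_symmetry_on_symmetric_system(self, symmetric_system,
                                                   rng):
        state = ak.AlchemicalState(lam=0.5, lam1=0.5, lam2=0.5)
        x = symmetric_system.coordinates + rng.normal(0, 0.5, (2, 3))
        u_here = total_alchemical_energy(x, symmetric_system, state).energy
        u_there = total_alchemical_energy(
            ak.swap_transform(x, symmetric_system), symmetric_system,
            state).energy
        assert u_here == pytest.approx(u_there, abs=1e-9)


class TestLambdaSchedule:
    def test_even_spacing_with_midpoint_endpoint(self):
        states = ak.lambda_schedule(11, leg=1)
        np.testing.assert_allclose([s.lam for s in states],
                                   np.arange(11) * 0.05)
        assert states[-1].lam == 0.5

    def test_two_window_schedule(self):
        lams = [s.lam for s in ak.lambda_schedule(2)]
        assert lams == [0.0, 0.5]

    def test_legs_share_grid_and_differ_in_flag(self):
        leg1 = ak.lambda_schedule(7, leg=1)
        leg2 = ak.lambda_schedule(7, leg=2)
        assert [s.lam for s in leg1] == [s.lam for s in leg2]
        assert all(s.leg == 1 for s in leg1)
        assert all(s.leg == 2 for s in leg2)

    def test_softplus_family_meets_linear_at_endpoints(self):
        states = ak.lambda_schedule(6, family="softplus")
        assert states[0].lam1 == states[0].lam2 == 0.0
        assert states[-1].lam1 == pytest.approx(0.5)
        assert states[-1].lam2 == pytest.approx(0.5)
        assert all(s.lam2 <= s.lam1 + 1e-12 for s in states)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            ak.lambda_schedule(1)
        with pytest.raises(InvalidParameterError):
            ak.lambda_schedule(5, family="geometric")
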