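"""Langevin dynamics, annealing and replica exchange."""

import numpy as np
import pytest

import atmkit as ak
from atmkit.alchemy import AlchemicalPotential, lambda_schedule
from atmkit.constants import temperature_for_kt
from atmkit.energy import HarmonicTether, mm_energy
from atmkit.errors import InvalidParameterError, InvalidScheduleError
from atmkit.sampling import (ReplicaEnsemble, anneal_to_intermediate,
                             langevin_step, maxwell_velocities,
                             replica_exchange_sweep, run_atm_leg)


def _tether_energy_fn(k=1.0):
    term = HarmonicTether(0, center=(0.0, 0.0, 0.0), k=k)

    def energy_fn(x):
        return mm_energy(x, [term])

    return energy_fn


class TestLangevinStep:
    def test_equipartition_on_harmonic_well(self):
        """<x^2> = kT/k per component at equilibrium (kT = 1, k = 1)."""
        kT = 1.0
        temp = temperature_for_kt(kT)
        rng = np.random.default_rng(42)
        masses = np.array([12.0])
        x = np.zeros((1, 3))
        v = maxwell_velocities(x.shape, masses, temp, rng)
        energy_fn = _tether_energy_fn(k=1.0)
        force = None
        n_steps, stride = 200_000, 20
        sq = []
        for step in range(n_steps):
            x, v, force = langevin_step(x, v, energy_fn, masses, 4.0, 5.0,
                                        temp, rng, force=force)
            if step % stride == 0 and step > 5000:
                sq.append(np.mean(x * x))
        mean_sq = float(np.mean(sq))
        # ~1e4 near-independent samples of a chi-squared_1 variable
        n_eff = 2000.0
        se = np.sqrt(2.0 / 3.0) / np.sqrt(n_eff)
        assert abs(mean_sq - kT) < 3.0 * se

    def test_bit_identical_replay(self):
        temp = temperature_for_kt(1.0)
        masses = np.array([12.0, 12.0])
        energy_fn = _tether_energy_fn()

        def trajectory(seed):
            rng = np.random.default_rng(seed)
            x = np.array([[0.5, 0.0, 0.0], [0.0, 1.0, 0.0]])
            v = np.zeros_like(x)
            force = None
            for step in range(200):
                x, v, force = langevin_step(x, v, energy_fn, masses, 2.0,
                                            1.0, temp, rng, force=force)
            return x, v

        xa, va = trajectory(7)
        xb, vb = trajectory(7)
        np.testing.assert_array_equal(xa, xb)
        np.testing.assert_array_equal(va, vb)
        xc, _ = trajectory(8)
        assert not np.array_equal(xa, xc)

    def test_zero_temperature_descends_a_convex_well(self):
        rng = np.random.default_rng(0)
        masses = np.array([12.0])
        energy_fn = _tether_energy_fn(k=4.0)
        x = np.array([[2.0, -1.0, 0.5]])
        v = np.zeros_like(x)
        e0 = energy_fn(x)[0]
        force = None
        for _ in range(6000):
            x, v, force = langevin_step(x, v, energy_fn, masses, 1.0, 50.0,
                                        1e-12, rng, force=force)
        assert energy_fn(x)[0] < 1e-6 < e0


class TestAnneal:
    def test_rejects_schedule_not_ending_at_midpoint(self, harmonic_system):
        run = ak.RunSpec(seed=0)
        schedule = lambda_schedule(5)[:-1]
        with pytest.raises(InvalidScheduleError):
            anneal_to_intermediate(harmonic_system, schedule, 10, run,
                                   np.random.default_rng(0))

    def test_annealed_state_is_finite_at_every_window(self, harmonic_system):
        run = ak.RunSpec(seed=0)
        schedule = lambda_schedule(5)
        coords = anneal_to_intermediate(harmonic_system, schedule, 100, run,
                                        np.random.default_rng(1))
        for leg in (1, 2):
            pot = AlchemicalPotential(harmonic_system,
                                      lambda_schedule(5, leg=leg))
            e, _, _ = pot.energy_gradient(
                np.repeat(coords[None], 5, axis=0))
            assert np.all(np.isfinite(e))

    def test_deterministic_under_fixed_seed(self, harmonic_system):
        run = ak.RunSpec(seed=0)
        schedule = lambda_schedule(3)
        a = anneal_to_intermediate(harmonic_system, schedule, 50, run,
                                   np.random.default_rng(5))
        b = anneal_to_intermediate(harmonic_system, schedule, 50, run,
                                   np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


def _frozen_two_replica_ensemble(system, u_target_second):
    """Two replicas: one at the system minimum (u=0), one displaced so the
    perturbation energy equals ``u_target_second`` (u = -1.5 x^2 on the
    4->1 harmonic system)."""
    states = [
        ak.AlchemicalState(lam=0.0, lam1=0.0, lam2=0.0),
        ak.AlchemicalState(lam=0.5, lam1=0.5, lam2=0.5),
    ]
    x0 = system.coordinates.copy()
    x1 = system.coordinates.copy()
    x1[0, 0] += np.sqrt(-u_target_second / 1.5)
    coords = np.stack([x0, x1])
    return ReplicaEnsemble(states=states, coords=coords,
                           velocities=np.zeros_like(coords))


class TestReplicaExchange:
    def test_identical_states_always_swap(self, harmonic_system):
        states = [ak.AlchemicalState(lam=0.2, lam1=0.2, lam2=0.2)] * 2
        coords = np.stack([harmonic_system.coordinates,
                           harmonic_system.coordinates + 0.3])
        ens = ReplicaEnsemble(states=states, coords=coords,
                              velocities=np.zeros_like(coords))
        rng = np.random.default_rng(0)
        for _ in range(50):
            ens.sweep_index = 0  # keep attempting the (0, 1) pair
            replica_exchange_sweep(ens, harmonic_system, 1.0, rng)
        assert ens.attempts[0] == 50
        assert ens.accepts[0] == 50

    def test_fixed_delta_acceptance_rate(self, harmonic_system):
        """Delta = 2 kT: empirical acceptance ~ e^-2 over 10^4 attempts."""
        rng = np.random.default_rng(123)
        n, accepted = 10_000, 0
        for _ in range(n):
            # u_2 = -4 kT at lam 0 vs 0.5 => Delta = (0-0.5)(u2-u1) = +2 kT
            ens = _frozen_two_replica_ensemble(harmonic_system, -4.0)
            replica_exchange_sweep(ens, harmonic_system, 1.0, rng)
            accepted += int(ens.accepts[0])
        p = np.exp(-2.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(accepted / n - p) < 3.0 * se

    def test_frozen_chain_matches_boltzmann_occupancy(self, harmonic_system):
        """Long-run occupancy of a frozen 2-replica chain is Boltzmann."""
        rng = np.random.default_rng(99)
        delta = np.log(2.0)  # u2 = -2 ln 2
        ens = _frozen_two_replica_ensemble(harmonic_system, -4.0 * np.log(2.0)
                                           / 2.0)
        n_sweeps, in_original = 20_000, 0
        for _ in range(n_sweeps):
            ens.sweep_index = 0
            replica_exchange_sweep(ens, harmonic_system, 1.0, rng)
            in_original += int(ens.replica_ids[0] == 0)
        frac = in_original / n_sweeps
        expected = 1.0 / (1.0 + np.exp(-delta))  # pi(original) = 2/3
        # generous allowance for Markov-chain autocorrelation
        se = np.sqrt(expected * (1 - expected) / n_sweeps) * 3.0
        assert abs(frac - expected) < 3.0 * se

    def test_needs_two_replicas(self, harmonic_system):
        states = [ak.AlchemicalState(lam=0.0, lam1=0.0, lam2=0.0)]
        coords = harmonic_system.coordinates[None]
        ens = ReplicaEnsemble(states=states, coords=coords,
                              velocities=np.zeros_like(coords))
        with pytest.raises(InvalidParameterError):
            replica_exchange_sweep(ens, harmonic_system, 1.0,
                                   np.random.default_rng(0))


QUICK_RUN = dict(n_windows=5, n_steps=2000, exchange_interval=200,
                 sample_interval=200, anneal_steps=500, equil_steps=400)


class TestRunAtmLeg:
    def test_triplicate_returns_three_independent_series(self,
                                                         harmonic_system):
        run = ak.RunSpec(seed=4, replicate_count=3, **QUICK_RUN)
        samples = run_atm_leg(harmonic_system, 1, run)
        assert len(samples) == 3
        assert [s.replicate for s in samples] == [0, 1, 2]
        assert not np.array_equal(samples[0].u_series, samples[1].u_series)

    def test_symmetric_system_has_zero_mean_u_at_midpoint(
            self, symmetric_system):
        run = ak.RunSpec(seed=2, replicate_count=1, friction=10.0,
                         n_windows=5, n_steps=20000, exchange_interval=250,
                         sample_interval=250, anneal_steps=1000,
                         equil_steps=1000)
        s = run_atm_leg(symmetric_system, 1, run)[0]
        u_mid = s.u_series[-1]
        se = u_mid.std(ddof=1) / np.sqrt(u_mid.size)
        assert abs(u_mid.mean()) < 4.0 * se

    def test_exchange_acceptance_strictly_between_zero_and_one(
            self, harmonic_system):
        run = ak.RunSpec(seed=1, replicate_count=1, n_windows=11,
                         n_steps=10000, exchange_interval=250,
                         sample_interval=500, anneal_steps=1100,
                         equil_steps=1000)
        s = run_atm_leg(harmonic_system, 1, run)[0]
        rates = s.exchange_acceptance
        assert np.all(rates[np.isfinite(rates)] > 0.0)
        assert np.nanmean(rates) < 1.0

    def test_bit_identical_replay(self, harmonic_system):
        run = ak.RunSpec(seed=6, replicate_count=1, **QUICK_RUN)
        a = run_atm_leg(harmonic_system, 1, run)[0]
        b = run_atm_leg(harmonic_system, 1, run)[0]
        np.testing.assert_array_equal(a.u_series, b.u_series)
        np.testing.assert_array_equal(a.bias_matrix, b.bias_matrix)

    def test_invalid_leg_rejected(self, harmonic_system):
        run = ak.RunSpec(seed=0, **QUICK_RUN)
        with pytest.raises(InvalidParameterError):
            run_atm_leg(harmonic_system, 3, run)


class TestRunSpec:
    def test_intervals_must_divide_steps(self):
        with pytest.raises(InvalidParameterError):
            ak.RunSpec(n_steps=1000, exchange_interval=300)
        with pytest.raises(InvalidParameterError):
            ak.RunSpec(n_steps=1000, sample_interval=301,
                       exchange_interval=250)

    def test_positive_timestep_required(self):
        with pytest.raises(InvalidParameterError):
            ak.RunSpec(timestep_fs=0.0)

    def test_roundtrip_dict(self):
        run = ak.RunSpec(seed=3, n_steps=4000, exchange_interval=200,
                         sample_interval=400)
        assert ak.RunSpec(**run.to_dict()) == run
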