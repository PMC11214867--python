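"""Langevin dynamics and Hamiltonian replica exchange over lambda windows.

One ATM leg is sampled as: anneal the system from lambda = 0 to the
symmetric intermediate lambda = 1/2, seed every replica from the annealed
configuration, then alternate batched BAOAB Langevin dynamics with
synchronous neighbor-swap sweeps (even/odd pair alternation).  Perturbation
energies recorded at each window feed the UWHAM estimator.

All randomness flows from named, seeded streams: a fixed (seed, leg,
replicate) triple replays bit-identically, including exchange decisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alchemy import (AlchemicalPotential, AlchemicalState, alchemical_bias,
                      lambda_schedule, softcore, swap_transform)
from .constants import KB, KCAL_PER_MOL_TO_MD
from .errors import (IncompleteSamplingError, IntegrationFailureError,
                     InvalidParameterError, InvalidScheduleError)
from .systems import ToySystem
from .uwham import PerturbationSamples

logger = logging.getLogger(__name__)

__all__ = ["RunSpec", "ReplicaEnsemble", "langevin_step", "maxwell_velocities",
           "anneal_to_intermediate", "replica_exchange_sweep", "run_atm_leg"]


@dataclass(frozen=True)
class RunSpec:
    """Desk-scale simulation budget for one ATM leg.

    Defaults (11 windows x 20,000 production steps, exchange every 250,
    sample every 250) run in seconds per leg on one CPU while leaving
    samples roughly one position-decorrelation time apart.
    """

    timestep_fs: float = 4.0
    friction: float = 1.0          # 1/ps
    n_steps: int = 20000           # production steps per replica
    exchange_interval: int = 250
    sample_interval: int = 250
    anneal_steps: int = 2500
    equil_steps: int = 2500        # post-anneal, pre-production relaxation
    replicate_count: int = 3
    seed: int = 0
    n_windows: int = 11
    family: str = "linear"

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise InvalidParameterError("timestep must be positive")
        if self.friction < 0:
            raise InvalidParameterError("friction must be non-negative")
        for name in ("n_steps", "exchange_interval", "sample_interval",
                     "anneal_steps", "equil_steps"):
            if getattr(self, name) < 0 or (name in ("n_steps",) and
                                           getattr(self, name) == 0):
                raise InvalidParameterError(f"{name} must be positive")
        if self.n_steps % self.exchange_interval:
            raise InvalidParameterError(
                "exchange_interval must divide n_steps")
        if self.n_steps % self.sample_interval:
            raise InvalidParameterError("sample_interval must divide n_steps")
        if self.replicate_count < 1:
            raise InvalidParameterError("replicate_count must be >= 1")
        if self.n_windows < 2:
            raise InvalidParameterError("need at least two lambda windows")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "timestep_fs", "friction", "n_steps", "exchange_interval",
            "sample_interval", "anneal_steps", "equil_steps",
            "replicate_count", "seed", "n_windows", "family")}


def maxwell_velocities(shape, masses: np.ndarray, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities in A/ps for coordinates of ``shape``."""
    kT_md = KB * temperature * KCAL_PER_MOL_TO_MD
    sigma = np.sqrt(kT_md / np.asarray(masses))[..., None]
    return rng.normal(size=shape) * sigma


def langevin_step(coords: np.ndarray, velocities: np.ndarray, energy_fn,
                  masses: np.ndarray, timestep_fs: float, friction: float,
                  temperature: float, rng: np.random.Generator,
                  force: np.ndarray | None = None, step_index: int = 0):
    """One BAOAB-splitting Langevin update.

    ``energy_fn(coords) -> (energy, gradient)`` in kcal/mol and
    kcal/mol/A; coordinates in A, velocities in A/ps, masses in amu,
    friction in 1/ps.  Pass the cached ``force`` (the negative gradient of
    the previous step) to avoid recomputing it; the new force is returned.

    Returns ``(coords', velocities', force')``.
    """
    dt = timestep_fs * 1e-3  # ps
    m = np.asarray(masses, dtype=float)[..., None]
    inv_m = KCAL_PER_MOL_TO_MD / m
    if force is None:
        _, grad = energy_fn(coords)
        force = -np.asarray(grad)
    v = velocities + 0.5 * dt * force * inv_m
    x = coords + 0.5 * dt * v
    if friction > 0:
        c1 = np.exp(-friction * dt)
        kT_md = KB * temperature * KCAL_PER_MOL_TO_MD
        c2 = np.sqrt((1.0 - c1 * c1) * kT_md / m)
        v = c1 * v + c2 * rng.normal(size=v.shape)
    x = x + 0.5 * dt * v
    _, grad = energy_fn(x)
    grad = np.asarray(grad)
    if not np.all(np.isfinite(grad)):
        raise IntegrationFailureError("non-finite gradient during dynamics",
                                      step=step_index)
    force = -grad
    v = v + 0.5 * dt * force * inv_m
    return x, v, force


def _run_dynamics(coords, velocities, energy_fn, masses, spec: RunSpec,
                  temperature, rng, n_steps, force=None, sample_hook=None,
                  sample_interval=None, step_offset=0):
    """Inner loop shared by annealing, equilibration and production.

    ``step_offset`` carries the global step count across chunks so a
    sampling stride longer than one chunk still fires.
    """
    for step in range(n_steps):
        coords, velocities, force = langevin_step(
            coords, velocities, energy_fn, masses, spec.timestep_fs,
            spec.friction, temperature, rng, force=force, step_index=step)
        if (sample_hook is not None and sample_interval
                and (step_offset + step + 1) % sample_interval == 0):
            sample_hook(coords)
    return coords, velocities, force


def anneal_to_intermediate(system: ToySystem,
                           schedule: list[AlchemicalState],
                           steps_per_state: int, run: RunSpec,
                           rng: np.random.Generator, mode: str = "mm",
                           surrogates=None,
                           coords0: np.ndarray | None = None) -> np.ndarray:
    """Drag the system along the schedule to lambda = 1/2.

    Runs ``steps_per_state`` Langevin steps at each window in order and
    returns the final configuration, which seeds every replica of the leg.
    The schedule must end at the symmetric intermediate.
    """
    if abs(schedule[-1].lam - 0.5) > 1e-12:
        raise InvalidScheduleError("annealing schedule must end at lambda = 1/2")
    coords = np.array(system.coordinates if coords0 is None else coords0,
                      dtype=float, copy=True)
    velocities = maxwell_velocities(coords.shape, system.masses,
                                    system.temperature, rng)
    for state in schedule:
        pot = AlchemicalPotential(system, [state], mode, surrogates)

        def energy_fn(x, _pot=pot):
            e, g, _ = _pot.energy_gradient(x[None])
            return e[0], g[0]

        coords, velocities, _ = _run_dynamics(
            coords, velocities, energy_fn, system.masses, run,
            system.temperature, rng, steps_per_state)
    return coords


@dataclass
class ReplicaEnsemble:
    """Replica coordinates indexed by alchemical state.

    Row k of ``coords`` always holds the replica currently assigned to
    ``states[k]``; an accepted swap exchanges rows (and ``replica_ids``
    tracks which walker sits where).  ``attempts``/``accepts`` count swap
    statistics per neighbor pair.
    """

    states: list[AlchemicalState]
    coords: np.ndarray                # (K, N, 3)
    velocities: np.ndarray            # (K, N, 3)
    replica_ids: np.ndarray = None    # (K,)
    attempts: np.ndarray = None       # (K-1,)
    accepts: np.ndarray = None
    sweep_index: int = 0

    def __post_init__(self):
        k = len(self.states)
        if self.coords.shape[0] != k or self.velocities.shape[0] != k:
            raise InvalidParameterError("one replica per state required")
        if self.replica_ids is None:
            self.replica_ids = np.arange(k)
        if self.attempts is None:
            self.attempts = np.zeros(max(k - 1, 0), dtype=int)
        if self.accepts is None:
            self.accepts = np.zeros(max(k - 1, 0), dtype=int)

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0,
                            self.accepts / np.maximum(self.attempts, 1),
                            np.nan)


def replica_exchange_sweep(ensemble: ReplicaEnsemble, system: ToySystem,
                           kT: float, rng: np.random.Generator,
                           mode: str = "mm", surrogates=None,
                           potential: AlchemicalPotential | None = None,
                           u: np.ndarray | None = None) -> ReplicaEnsemble:
    """One synchronous neighbor-swap sweep (even/odd pair alternation).

    The swap of the replicas at states i and j is accepted with probability
    min(1, exp(-[W_i(u_j) + W_j(u_i) - W_i(u_i) - W_j(u_j)]/kT)), with W
    evaluated on the soft-core capped perturbation energies.  Statistics
    are updated in place; the (mutated) ensemble is returned.
    """
    if len(ensemble.states) < 2:
        raise InvalidParameterError("replica exchange needs >= 2 replicas")
    pot = potential if potential is not None else AlchemicalPotential(
        system, ensemble.states, mode, surrogates)
    if u is None:
        _, _, u = pot.energy_gradient(ensemble.coords)
    u_sc = np.asarray(softcore(np.asarray(u, dtype=float), pot._sc))
    w_self = pot.bias(u_sc)                       # W_k(u_k)
    start = ensemble.sweep_index % 2
    k = len(ensemble.states)
    for i in range(start, k - 1, 2):
        j = i + 1
        delta = (alchemical_bias(u_sc[j], pot.states[i])
                 + alchemical_bias(u_sc[i], pot.states[j])
                 - w_self[i] - w_self[j]) / kT
        ensemble.attempts[i] += 1
        accept = delta <= 0 or rng.random() < np.exp(-min(float(delta), 700.0))
        if accept:
            ensemble.accepts[i] += 1
            for arr in (ensemble.coords, ensemble.velocities):
                arr[[i, j]] = arr[[j, i]]
            ensemble.replica_ids[[i, j]] = ensemble.replica_ids[[j, i]]
            u_sc[[i, j]] = u_sc[[j, i]]
            w_self[i] = alchemical_bias(u_sc[i], pot.states[i])
            w_self[j] = alchemical_bias(u_sc[j], pot.states[j])
    ensemble.sweep_index += 1
    return ensemble


def run_atm_leg(system: ToySystem, leg: int, run: RunSpec, mode: str = "mm",
                surrogates=None) -> list[PerturbationSamples]:
    """Sample one ATM leg; returns one PerturbationSamples per replicate.

    Pipeline per replicate: anneal from lambda = 0 to 1/2, seed all windows
    from the annealed configuration, equilibrate, then alternate dynamics
    and exchange sweeps while recording the perturbation energy u at every
    window.  Leg 2 starts from the swapped configuration so its lambda = 0
    ensemble is the transferred (reverse) state.
    """
    if leg not in (1, 2):
        raise InvalidParameterError("leg must be 1 or 2")
    schedule = lambda_schedule(run.n_windows, leg=leg, family=run.family)
    results = []
    for rep in range(run.replicate_count):
        results.append(_run_one_replicate(system, leg, run, schedule, rep,
                                          mode, surrogates))
    return results


def _run_one_replicate(system, leg, run: RunSpec, schedule, rep, mode,
                       surrogates) -> PerturbationSamples:
    rng = np.random.default_rng(
        np.random.SeedSequence([int(run.seed), int(leg), int(rep), 0xA7]))
    kT = system.kT
    coords0 = system.coordinates
    if leg == 2:
        coords0 = swap_transform(coords0, system)
    steps_per_state = max(run.anneal_steps // len(schedule), 1)
    x_mid = anneal_to_intermediate(system, schedule, steps_per_state, run,
                                   rng, mode, surrogates, coords0=coords0)
    k = len(schedule)
    coords = np.repeat(x_mid[None], k, axis=0)
    velocities = maxwell_velocities(coords.shape, system.masses,
                                    system.temperature, rng)
    ensemble = ReplicaEnsemble(states=schedule, coords=coords,
                               velocities=velocities)
    pot = AlchemicalPotential(system, schedule, mode, surrogates)

    def batch_energy(x):
        e, g, _ = pot.energy_gradient(x)
        return e, g

    force = None
    # equilibration: dynamics + exchanges, nothing recorded
    n_eq_cycles = max(run.equil_steps // run.exchange_interval, 0)
    for _ in range(n_eq_cycles):
        ensemble.coords, ensemble.velocities, force = _run_dynamics(
            ensemble.coords, ensemble.velocities, batch_energy,
            system.masses, run, system.temperature, rng,
            run.exchange_interval, force=force)
        replica_exchange_sweep(ensemble, system, kT, rng, mode, surrogates,
                               potential=pot)
        force = None  # rows may have been swapped
    ensemble.attempts[:] = 0
    ensemble.accepts[:] = 0

    u_series: list[np.ndarray] = []
    n_cycles = run.n_steps // run.exchange_interval

    def record(x):
        _, _, u = pot.energy_gradient(x)
        u_series.append(np.asarray(u))

    for cycle in range(n_cycles):
        ensemble.coords, ensemble.velocities, force = _run_dynamics(
            ensemble.coords, ensemble.velocities, batch_energy,
            system.masses, run, system.temperature, rng,
            run.exchange_interval, force=force,
            sample_hook=record, sample_interval=run.sample_interval,
            step_offset=cycle * run.exchange_interval)
        replica_exchange_sweep(ensemble, system, kT, rng, mode, surrogates,
                               potential=pot)
        force = None
    if not u_series:
        raise IncompleteSamplingError(
            "no samples recorded: sample_interval exceeds n_steps")
    u_per_state = np.stack(u_series, axis=1)      # (K, n_samples)
    logger.debug("leg %d rep %d: mean exchange acceptance %.3f", leg, rep,
                 float(np.nanmean(ensemble.acceptance_rates)))
    u_flat = u_per_state.reshape(-1)              # state-major order
    counts = np.full(k, u_per_state.shape[1], dtype=int)
    bias = pot.bias_matrix(u_flat) / kT
    return PerturbationSamples(
        bias_matrix=bias, sample_counts=counts,
        lambdas=np.array([s.lam for s in schedule]),
        leg=leg, replicate=rep, kT=kT, u_series=u_per_state,
        exchange_acceptance=ensemble.acceptance_rates,
    )
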