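"""The Alchemical Transfer Method core.

ATM estimates a relative binding free energy by biasing a single collective
variable: the perturbation energy u(x) = E(swap(x)) - E(x), where swap
rigidly translates ligand A by the site-to-bulk displacement and ligand B
back.  Two legs, each running lambda from 0 to the symmetric intermediate
1/2 (leg 1 from the physical bound state, leg 2 from the swapped state),
meet at the alchemical midpoint; ddG = dG_leg1 - dG_leg2.

The bias applied to u is the standard soft-core capped softplus

    W(u_sc) = lam2 u_sc + (lam2 - lam1)/alpha * ln[1 + exp(-alpha (u_sc - u0))] + w0

which reduces exactly to the linear coupling lam * u_sc + w0 when
lam1 = lam2 = lam.  The soft-core transform caps large positive u at umax
with unit slope at the joint u = uc, keeping the lambda = 1/2 states finite
even across steric clashes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyResult, hybrid_energy
from .errors import InvalidParameterError
from .systems import ToySystem

__all__ = [
    "SoftCoreParams", "AlchemicalState", "swap_transform",
    "perturbation_energy", "softcore", "softcore_derivative",
    "alchemical_bias", "alchemical_bias_derivative",
    "total_alchemical_energy", "lambda_schedule", "AlchemicalPotential",
]


@dataclass(frozen=True)
class SoftCoreParams:
    """Rational soft-core cap: identity below ``uc``, bounded by ``umax``."""

    umax: float = 200.0
    uc: float = 100.0
    a: float = 0.0625

    def __post_init__(self):
        if not (self.umax > self.uc):
            raise InvalidParameterError("soft-core requires umax > uc")
        if self.a <= 0:
            raise InvalidParameterError("soft-core exponent a must be positive")


@dataclass(frozen=True)
class AlchemicalState:
    """One lambda window of an ATM leg.

    ``lam`` indexes the window on [0, 1/2]; ``lam1``/``lam2`` are the
    softplus slopes (equal for linear coupling), ``alpha`` (1/(kcal/mol)),
    ``u0`` and ``w0`` (kcal/mol) shape the softplus, and ``leg`` records
    which transfer direction the window belongs to.
    """

    lam: float
    lam1: float
    lam2: float
    alpha: float = 0.1
    u0: float = 110.0
    w0: float = 0.0
    leg: int = 1
    softcore: SoftCoreParams = field(default_factory=SoftCoreParams)

    def __post_init__(self):
        if not (0.0 <= self.lam <= 0.5):
            raise InvalidParameterError("lambda must lie in [0, 1/2]")
        if self.alpha < 0:
            raise InvalidParameterError("alpha must be non-negative")
        if self.alpha == 0 and self.lam1 != self.lam2:
            raise InvalidParameterError(
                "alpha = 0 is undefined unless lam1 == lam2")
        if self.leg not in (1, 2):
            raise InvalidParameterError("leg must be 1 or 2")


def swap_transform(coords: np.ndarray, system: ToySystem) -> np.ndarray:
    """Transfer each ligand rigidly to the opposite end of the displacement.

    A ligand whose centroid currently sits nearer the binding-site center
    is translated by +displacement (site -> bulk); one nearer the bulk
    center is translated by -displacement.  In the physical state this
    moves ligand A by +d and ligand B by -d; applied to an already-swapped
    configuration it undoes the transfer, so the transform is an involution
    (exact up to the floating-point roundoff of the translation).
    Environment particles are untouched.
    """
    if set(system.ligand_a) & set(system.ligand_b):
        raise InvalidParameterError("ligand groups overlap")
    out = np.array(coords, dtype=float, copy=True)
    d = system.displacement
    for group in (system.ligand_a, system.ligand_b):
        idx = np.asarray(group, dtype=int)
        centroid = out[..., idx, :].mean(axis=-2)
        to_site = np.sum((centroid - system.site_center) ** 2, axis=-1)
        to_bulk = np.sum((centroid - system.bulk_center) ** 2, axis=-1)
        sign = np.where(to_site <= to_bulk, 1.0, -1.0)
        out[..., idx, :] += sign[..., None, None] * d
    return out


def perturbation_energy(coords: np.ndarray, system: ToySystem,
                        mode: str = "mm",
                        surrogates=None) -> np.ndarray:
    """u(x) = E(swap(x)) - E(x), the single collective variable ATM biases.

    Exactly antisymmetric under the swap: u(swap(x)) = -u(x).
    """
    e0 = hybrid_energy(coords, system, mode, surrogates,
                       with_gradient=False).energy
    e1 = hybrid_energy(swap_transform(coords, system), system, mode,
                       surrogates, with_gradient=False).energy
    return e1 - e0


# --------------------------------------------------------------------------
# soft-core and softplus bias
# --------------------------------------------------------------------------

def _softcore_f(y: np.ndarray, a: float):
    """f(y) = (z^(1/a) - 1)/(z^(1/a) + 1) with z = 1 + 2ay + 2(ay)^2.

    f(0) = 0 with f'(0) = 1 (unit slope at the joint) and f -> 1 as
    y -> infinity, which caps the soft-core at umax.  Returns (f, f').
    """
    ay = a * y
    z = 1.0 + 2.0 * ay + 2.0 * ay * ay
    with np.errstate(over="ignore"):
        g = z ** (1.0 / a)
    f = np.where(np.isfinite(g), (g - 1.0) / (g + 1.0), 1.0)
    with np.errstate(over="ignore", invalid="ignore"):
        dg = (1.0 / a) * z ** (1.0 / a - 1.0) * (2.0 * a + 4.0 * a * ay)
        fp = np.where(np.isfinite(g), 2.0 * dg / (g + 1.0) ** 2, 0.0)
    return f, fp


def softcore(u: np.ndarray | float, sc: SoftCoreParams) -> np.ndarray | float:
    """Cap the perturbation energy: identity for u <= uc, bounded by umax.

    C1 everywhere (unit slope at u = uc), strictly increasing, and
    approaching ``umax`` as u -> +infinity.
    """
    u_arr = np.asarray(u, dtype=float)
    span = sc.umax - sc.uc
    y = np.maximum(u_arr - sc.uc, 0.0) / span
    f, _ = _softcore_f(y, sc.a)
    out = np.where(u_arr > sc.uc, sc.uc + span * f, u_arr)
    return out if isinstance(u, np.ndarray) else float(out)


def softcore_derivative(u: np.ndarray | float,
                        sc: SoftCoreParams) -> np.ndarray | float:
    """d u_sc / d u; equals 1 on the identity branch and at the joint."""
    u_arr = np.asarray(u, dtype=float)
    span = sc.umax - sc.uc
    y = np.maximum(u_arr - sc.uc, 0.0) / span
    _, fp = _softcore_f(y, sc.a)
    out = np.where(u_arr > sc.uc, fp, 1.0)
    return out if isinstance(u, np.ndarray) else float(out)


def _softplus(x: np.ndarray) -> np.ndarray:
    """ln(1 + e^x), overflow-safe."""
    return np.logaddexp(0.0, x)


def alchemical_bias(u_sc: np.ndarray | float,
                    state: AlchemicalState) -> np.ndarray | float:
    """The softplus alchemical bias W(u_sc) of one window (kcal/mol).

    W = lam2 u_sc + (lam2 - lam1)/alpha ln[1 + exp(-alpha (u_sc - u0))] + w0,
    computed with a log-sum-exp formulation; reduces exactly to the linear
    coupling lam u_sc + w0 when lam1 == lam2.  Its slope is the convex
    combination lam1*s + lam2*(1-s) with s = sigmoid(-alpha (u_sc - u0)),
    so W interpolates between slope lam1 (very favorable u) and slope lam2
    (very unfavorable u) and is monotone whenever lam1, lam2 >= 0.
    """
    u_arr = np.asarray(u_sc, dtype=float)
    if state.lam1 == state.lam2:
        out = state.lam1 * u_arr + state.w0
    else:
        out = (state.lam2 * u_arr
               + (state.lam2 - state.lam1) / state.alpha
               * _softplus(-state.alpha * (u_arr - state.u0))
               + state.w0)
    return out if isinstance(u_sc, np.ndarray) else float(out)


def alchemical_bias_derivative(u_sc: np.ndarray | float,
                               state: AlchemicalState) -> np.ndarray | float:
    """d W / d u_sc = lam1 s + lam2 (1 - s), s = sigmoid(-alpha (u_sc - u0))."""
    u_arr = np.asarray(u_sc, dtype=float)
    if state.lam1 == state.lam2:
        out = np.full_like(u_arr, state.lam1)
    else:
        from scipy.special import expit
        s = expit(-state.alpha * (u_arr - state.u0))
        out = state.lam1 * s + state.lam2 * (1.0 - s)
    return out if isinstance(u_sc, np.ndarray) else float(out)


def total_alchemical_energy(coords: np.ndarray, system: ToySystem,
                            state: AlchemicalState, mode: str = "mm",
                            surrogates=None) -> EnergyResult:
    """U_lambda = E(x) + W(softcore(u(x))) with its chain-rule gradient.

    At lam1 = lam2 = 0 with w0 = 0 the bias vanishes and U equals the plain
    (MM or hybrid) energy.  The returned components carry the unbiased
    energy, u, u_sc and W for diagnostics.
    """
    res0 = hybrid_energy(coords, system, mode, surrogates)
    res1 = hybrid_energy(swap_transform(coords, system), system, mode,
                         surrogates)
    u = res1.energy - res0.energy
    u_sc = softcore(u, state.softcore)
    w = alchemical_bias(u_sc, state)
    dw = (alchemical_bias_derivative(u_sc, state)
          * softcore_derivative(u, state.softcore))
    energy = res0.energy + w
    grad = res0.gradient + np.asarray(dw)[..., None, None] * (
        res1.gradient - res0.gradient)
    return EnergyResult(energy, grad, components={
        "unbiased": res0.energy, "u": u, "u_sc": u_sc, "bias": w})


def lambda_schedule(n_windows: int = 11, leg: int = 1,
                    family: str = "linear",
                    softcore_params: SoftCoreParams | None = None,
                    alpha: float = 0.1, u0: float = 110.0,
                    w0: float = 0.0) -> list[AlchemicalState]:
    """Evenly spaced lambda windows from 0 to the symmetric midpoint 1/2.

    ``family='linear'`` sets lam1 = lam2 = lam (linear coupling);
    ``family='softplus'`` ramps lam2 = 2 lam^2 below lam1 = lam so the two
    meet at the midpoint.  Both legs share the same grid and differ only in
    the direction flag.
    """
    if n_windows < 2:
        raise InvalidParameterError("need at least two lambda windows")
    if family not in ("linear", "softplus"):
        raise InvalidParameterError(f"unknown schedule family {family!r}")
    sc = softcore_params if softcore_params is not None else SoftCoreParams()
    states = []
    for lam in np.linspace(0.0, 0.5, n_windows):
        lam = float(lam)
        if family == "linear":
            lam1 = lam2 = lam
        else:
            lam1, lam2 = lam, 2.0 * lam * lam
        states.append(AlchemicalState(lam=lam, lam1=lam1, lam2=lam2,
                                      alpha=alpha, u0=u0, w0=w0, leg=leg,
                                      softcore=sc))
    return states


class AlchemicalPotential:
    """Batched U_lambda evaluation for a set of windows sharing one system.

    Evaluates a batch of replica coordinates, one per alchemical state, in
    a single vectorized pass; this is what the replica-exchange driver
    steps on.  Also usable with a single state for scalar evaluation.
    """

    def __init__(self, system: ToySystem, states: list[AlchemicalState],
                 mode: str = "mm", surrogates=None):
        if not states:
            raise InvalidParameterError("need at least one state")
        self.system = system
        self.states = list(states)
        self.mode = mode
        self.surrogates = surrogates
        self._lam1 = np.array([s.lam1 for s in states])
        self._lam2 = np.array([s.lam2 for s in states])
        self._alpha = np.array([s.alpha for s in states])
        self._u0 = np.array([s.u0 for s in states])
        self._w0 = np.array([s.w0 for s in states])
        self._sc = states[0].softcore
        if any(s.softcore != self._sc for s in states):
            raise InvalidParameterError(
                "all windows of one leg must share soft-core parameters")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @staticmethod
    def _bias_broadcast(lam1, lam2, alpha, u0, w0, u_sc):
        linear = lam1 == lam2
        safe_alpha = np.where(alpha > 0, alpha, 1.0)
        soft = np.where(linear, 0.0,
                        (lam2 - lam1) / safe_alpha
                        * _softplus(-alpha * (u_sc - u0)))
        return np.where(linear, lam1 * u_sc + w0, lam2 * u_sc + soft + w0)

    def bias(self, u_sc: np.ndarray) -> np.ndarray:
        """Vectorized W per state; u_sc is aligned with the state axis (K,)."""
        return self._bias_broadcast(self._lam1, self._lam2, self._alpha,
                                    self._u0, self._w0, u_sc)

    def bias_matrix(self, u: np.ndarray) -> np.ndarray:
        """W_k(softcore(u_n)) for every state k and sample n: shape (K, N)."""
        u_sc = np.asarray(softcore(np.asarray(u, dtype=float), self._sc))
        return self._bias_broadcast(
            self._lam1[:, None], self._lam2[:, None], self._alpha[:, None],
            self._u0[:, None], self._w0[:, None], u_sc[None, :])

    def energy_gradient(self, coords: np.ndarray):
        """(U (K,), grad (K,N,3), u (K,)) for one batch of replica coords."""
        res0 = hybrid_energy(coords, self.system, self.mode, self.surrogates)
        swapped = swap_transform(coords, self.system)
        res1 = hybrid_energy(swapped, self.system, self.mode, self.surrogates)
        u = res1.energy - res0.energy
        u_sc = np.asarray(softcore(u, self._sc))
        dusc = np.asarray(softcore_derivative(u, self._sc))
        w = self.bias(u_sc)
        from scipy.special import expit
        s = expit(-self._alpha * (u_sc - self._u0))
        dw_dusc = np.where(self._lam1 == self._lam2, self._lam1,
                           self._lam1 * s + self._lam2 * (1.0 - s))
        energy = res0.energy + w
        grad = res0.gradient + (dw_dusc * dusc)[..., None, None] * (
            res1.gradient - res0.gradient)
        return energy, grad, u
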