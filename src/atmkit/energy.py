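"""Toy molecular-mechanics energies and the hybrid surrogate/MM potential.

The MM side is a small set of analytic potential terms (bonds, tethers,
dual-well tethers, Lennard-Jones and Coulomb pairs, cosine torsions), each
with an exact gradient, evaluated on coordinate arrays of shape
``(..., n_particles, 3)`` so that a batch of replicas is a single call.

The hybrid mode implements mechanical embedding: for each ligand, every MM
term whose participants all lie inside that ligand's index group is removed
and replaced by a smooth surrogate potential of the ligand's internal
geometry.  Ligand-environment and environment-environment terms are left
untouched, so the hybrid/MM difference is exactly the sum over ligands of
(surrogate - MM intramolecular).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .constants import COULOMB_CONSTANT
from .errors import (ClassificationError, InvalidParameterError,
                     SingularGeometryError)

if TYPE_CHECKING:  # pragma: no cover
    from .systems import ToySystem

__all__ = [
    "PotentialTerm", "HarmonicBond", "HarmonicTether", "DualWellTether",
    "LennardJonesPair", "CoulombPair", "TorsionCosine", "SurrogateParams",
    "EnergyResult", "mm_energy", "surrogate_energy", "hybrid_energy",
    "classify_terms", "term_from_dict",
]

_COINCIDENCE_TOL = 1e-8


# --------------------------------------------------------------------------
# potential terms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialTerm:
    """Base class; concrete terms implement :meth:`accumulate`."""

    #: True for terms anchored to external space (tethers): they encode the
    #: host/solvent field, so they are never ligand-intramolecular even
    #: when their particle belongs to a ligand group.
    external_field = False

    @property
    def participants(self) -> tuple[int, ...]:  # pragma: no cover
        raise NotImplementedError

    def accumulate(self, coords: np.ndarray,
                   grad: np.ndarray | None) -> np.ndarray:
        """Return the term energy (batch shape) and add its gradient in place."""
        raise NotImplementedError  # pragma: no cover

    def to_dict(self) -> dict:
        raise NotImplementedError  # pragma: no cover


def _pair_vectors(coords: np.ndarray, i: int, j: int):
    rij = coords[..., j, :] - coords[..., i, :]
    r = np.sqrt(np.sum(rij * rij, axis=-1))
    return rij, r


@dataclass(frozen=True)
class HarmonicBond(PotentialTerm):
    """0.5 * k * (r - r0)^2 between particles i and j."""

    i: int
    j: int
    k: float
    r0: float

    def __post_init__(self):
        if self.k < 0 or self.r0 < 0:
            raise InvalidParameterError("harmonic bond needs k >= 0, r0 >= 0")
        if self.i == self.j:
            raise InvalidParameterError("bond endpoints must differ")

    @property
    def participants(self) -> tuple[int, ...]:
        return (self.i, self.j)

    def accumulate(self, coords, grad):
        rij, r = _pair_vectors(coords, self.i, self.j)
        delta = r - self.r0
        energy = 0.5 * self.k * delta * delta
        if grad is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(r[..., None] > 0.0, rij / np.maximum(r, 1e-300)[..., None], 0.0)
            g = (self.k * delta)[..., None] * unit
            grad[..., self.j, :] += g
            grad[..., self.i, :] -= g
        return energy

    def to_dict(self):
        return {"kind": "harmonic_bond", "i": int(self.i), "j": int(self.j),
                "k": float(self.k), "r0": float(self.r0)}


@dataclass(frozen=True)
class HarmonicTether(PotentialTerm):
    """0.5 * k * |r_i - center|^2 anchoring one particle in space."""

    external_field = True

    i: int
    center: tuple[float, float, float]
    k: float

    def __post_init__(self):
        if self.k < 0:
            raise InvalidParameterError("tether needs k >= 0")

    @property
    def participants(self) -> tuple[int, ...]:
        return (self.i,)

    def accumulate(self, coords, grad):
        d = coords[..., self.i, :] - np.asarray(self.center, dtype=float)
        energy = 0.5 * self.k * np.sum(d * d, axis=-1)
        if grad is not None:
            grad[..., self.i, :] += self.k * d
        return energy

    def to_dict(self):
        return {"kind": "harmonic_tether", "i": int(self.i),
                "center": [float(v) for v in self.center],
                "k": float(self.k)}


@dataclass(frozen=True)
class DualWellTether(PotentialTerm):
    """The toy "host": the lower of two harmonic wells (site and bulk).

    A particle near the binding-site center feels 0.5*k_site*|r-site|^2 and
    a particle near the bulk center feels 0.5*k_bulk*|r-bulk|^2; the lower
    energy branch is active.  With well separations of tens of angstroms the
    branch boundary carries negligible Boltzmann weight, so each basin is an
    exact 3D harmonic well and basin free energies are available in closed
    form.  The gradient is discontinuous only on the (never sampled)
    equal-energy surface.
    """

    external_field = True

    i: int
    k_site: float
    k_bulk: float
    site_center: tuple[float, float, float]
    bulk_center: tuple[float, float, float]

    def __post_init__(self):
        if self.k_site <= 0 or self.k_bulk <= 0:
            raise InvalidParameterError("dual well needs positive spring constants")

    @property
    def participants(self) -> tuple[int, ...]:
        return (self.i,)

    def accumulate(self, coords, grad):
        ds = coords[..., self.i, :] - np.asarray(self.site_center, dtype=float)
        db = coords[..., self.i, :] - np.asarray(self.bulk_center, dtype=float)
        es = 0.5 * self.k_site * np.sum(ds * ds, axis=-1)
        eb = 0.5 * self.k_bulk * np.sum(db * db, axis=-1)
        use_site = es <= eb
        energy = np.where(use_site, es, eb)
        if grad is not None:
            g = np.where(use_site[..., None], self.k_site * ds, self.k_bulk * db)
            grad[..., self.i, :] += g
        return energy

    def to_dict(self):
        return {"kind": "dual_well_tether", "i": int(self.i),
                "k_site": float(self.k_site), "k_bulk": float(self.k_bulk),
                "site_center": [float(v) for v in self.site_center],
                "bulk_center": [float(v) for v in self.bulk_center]}


@dataclass(frozen=True)
class LennardJonesPair(PotentialTerm):
    """4*eps*[(sigma/r)^12 - (sigma/r)^6] for one particle pair."""

    i: int
    j: int
    epsilon: float
    sigma: float

    def __post_init__(self):
        if self.epsilon < 0 or self.sigma <= 0:
            raise InvalidParameterError("LJ needs epsilon >= 0 and sigma > 0")
        if self.i == self.j:
            raise InvalidParameterError("LJ endpoints must differ")

    @property
    def participants(self) -> tuple[int, ...]:
        return (self.i, self.j)

    def accumulate(self, coords, grad):
        rij, r = _pair_vectors(coords, self.i, self.j)
        if np.any(r < _COINCIDENCE_TOL):
            raise SingularGeometryError(
                f"coincident particles {self.i},{self.j} in LJ pair")
        sr6 = (self.sigma / r) ** 6
        energy = 4.0 * self.epsilon * (sr6 * sr6 - sr6)
        if grad is not None:
            # dE/dr = -(24 eps / r) (2 sr12 - sr6)
            dedr = -(24.0 * self.epsilon / r) * (2.0 * sr6 * sr6 - sr6)
            g = (dedr / r)[..., None] * rij
            grad[..., self.j, :] += g
            grad[..., self.i, :] -= g
        return energy

    def to_dict(self):
        return {"kind": "lennard_jones_pair", "i": int(self.i),
                "j": int(self.j), "epsilon": float(self.epsilon),
                "sigma": float(self.sigma)}


@dataclass(frozen=True)
class CoulombPair(PotentialTerm):
    """332.0637 * q_i q_j / (dielectric * r), charges in e, r in angstrom."""

    i: int
    j: int
    qi: float
    qj: float
    dielectric: float = 1.0

    def __post_init__(self):
        if self.dielectric <= 0:
            raise InvalidParameterError("dielectric must be positive")
        if self.i == self.j:
            raise InvalidParameterError("Coulomb endpoints must differ")

    @property
    def participants(self) -> tuple[int, ...]:
        return (self.i, self.j)

    def accumulate(self, coords, grad):
        rij, r = _pair_vectors(coords, self.i, self.j)
        if np.any(r < _COINCIDENCE_TOL):
            raise SingularGeometryError(
                f"coincident particles {self.i},{self.j} in Coulomb pair")
        pref = COULOMB_CONSTANT * self.qi * self.qj / self.dielectric
        energy = pref / r
        if grad is not None:
            g = (-pref / (r * r * r))[..., None] * rij
            grad[..., self.j, :] += g
            grad[..., self.i, :] -= g
        return energy

    def to_dict(self):
        return {"kind": "coulomb_pair", "i": int(self.i), "j": int(self.j),
                "qi": float(self.qi), "qj": float(self.qj),
                "dielectric": float(self.dielectric)}


@dataclass(frozen=True)
class TorsionCosine(PotentialTerm):
    """amplitude * (1 + cos(n*phi - phase)) over the i-j-k-l dihedral."""

    i: int
    j: int
    k: int
    l: int
    amplitude: float
    periodicity: int
    phase: float = 0.0

    def __post_init__(self):
        if len({self.i, self.j, self.k, self.l}) != 4:
            raise InvalidParameterError("torsion needs four distinct particles")
        if self.periodicity < 1:
            raise InvalidParameterError("torsion periodicity must be >= 1")

    @property
    def participants(self) -> tuple[int, ...]:
        return (self.i, self.j, self.k, self.l)

    def accumulate(self, coords, grad):
        b1 = coords[..., self.j, :] - coords[..., self.i, :]
        b2 = coords[..., self.k, :] - coords[..., self.j, :]
        b3 = coords[..., self.l, :] - coords[..., self.k, :]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.sqrt(np.sum(b2 * b2, axis=-1))
        # signed dihedral via atan2
        x = np.sum(n1 * n2, axis=-1)
        y = np.sum(np.cross(n1, n2) * b2, axis=-1) / np.maximum(b2n, 1e-300)
        phi = np.arctan2(y, x)
        arg = self.periodicity * phi - self.phase
        energy = self.amplitude * (1.0 + np.cos(arg))
        if grad is not None:
            dedphi = -self.amplitude * self.periodicity * np.sin(arg)
            n1sq = np.maximum(np.sum(n1 * n1, axis=-1), 1e-300)
            n2sq = np.maximum(np.sum(n2 * n2, axis=-1), 1e-300)
            dphi_di = (-b2n / n1sq)[..., None] * n1
            dphi_dl = (b2n / n2sq)[..., None] * n2
            c12 = (np.sum(b1 * b2, axis=-1) / np.maximum(b2n * b2n, 1e-300))[..., None]
            c32 = (np.sum(b3 * b2, axis=-1) / np.maximum(b2n * b2n, 1e-300))[..., None]
            dphi_dj = -(1.0 + c12) * dphi_di + c32 * dphi_dl
            dphi_dk = c12 * dphi_di - (1.0 + c32) * dphi_dl
            w = dedphi[..., None]
            grad[..., self.i, :] += w * dphi_di
            grad[..., self.j, :] += w * dphi_dj
            grad[..., self.k, :] += w * dphi_dk
            grad[..., self.l, :] += w * dphi_dl
        return energy

    def to_dict(self):
        return {"kind": "torsion_cosine", "i": int(self.i),
                "j": int(self.j), "k": int(self.k), "l": int(self.l),
                "amplitude": float(self.amplitude),
                "periodicity": int(self.periodicity),
                "phase": float(self.phase)}


_TERM_KINDS = {
    "harmonic_bond": HarmonicBond,
    "harmonic_tether": HarmonicTether,
    "dual_well_tether": DualWellTether,
    "lennard_jones_pair": LennardJonesPair,
    "coulomb_pair": CoulombPair,
    "torsion_cosine": TorsionCosine,
}


def term_from_dict(d: dict) -> PotentialTerm:
    """Rebuild a potential term from its :meth:`PotentialTerm.to_dict` form."""
    d = dict(d)
    kind = d.pop("kind", None)
    if kind not in _TERM_KINDS:
        raise InvalidParameterError(f"unknown potential term kind {kind!r}")
    cls = _TERM_KINDS[kind]
    for key in ("center", "site_center", "bulk_center"):
        if key in d:
            d[key] = tuple(float(v) for v in d[key])
    return cls(**d)


# --------------------------------------------------------------------------
# MM evaluation
# --------------------------------------------------------------------------

def mm_energy(coords: np.ndarray, terms: Iterable[PotentialTerm],
              subset: Sequence[int] | None = None,
              with_gradient: bool = True):
    """Total MM energy and exact gradient of a term list.

    Parameters
    ----------
    coords
        Array of shape ``(..., n_particles, 3)`` in angstrom; leading axes
        are treated as a batch.
    terms
        Potential terms to sum.
    subset
        If given, only terms whose participants all lie in ``subset`` are
        evaluated (used to extract ligand-intramolecular energies).
    with_gradient
        If False, skip gradient accumulation and return ``(energy, None)``.

    Returns
    -------
    (energy, gradient)
        ``energy`` has the batch shape, ``gradient`` the shape of ``coords``
        in kcal/mol/angstrom.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise InvalidParameterError("coordinates must be finite")
    n = coords.shape[-2]
    if subset is not None:
        allowed = frozenset(int(i) for i in subset)
        terms = [t for t in terms if allowed.issuperset(t.participants)]
    energy = np.zeros(coords.shape[:-2], dtype=float)
    grad = np.zeros_like(coords) if with_gradient else None
    for term in terms:
        for p in term.participants:
            if not (0 <= p < n):
                raise InvalidParameterError(
                    f"term participant {p} out of range for {n} particles")
        energy = energy + term.accumulate(coords, grad)
    return energy, grad


# --------------------------------------------------------------------------
# surrogate intramolecular potential
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateParams:
    """A fixed, smooth surrogate for a learned intramolecular potential.

    The energy is a weighted sum of Gaussian radial basis functions over all
    intra-ligand pairwise distances, with a C1 cosine switch at ``cutoff``.
    Weights are drawn once from a seeded generator, so the surrogate is a
    deterministic, rotation- and translation-invariant, gradient-bearing
    function of the ligand's internal geometry -- the same contract a neural
    network potential offers, at desk scale.
    """

    seed: int
    centers: tuple[float, ...]
    widths: tuple[float, ...]
    weights: tuple[float, ...]
    cutoff: float = 8.0
    switch_width: float = 1.0

    @classmethod
    def create(cls, seed: int, n_basis: int = 8, r_min: float = 0.8,
               r_max: float = 6.0, scale: float = 1.0,
               cutoff: float = 8.0) -> "SurrogateParams":
        """Draw basis weights from a named, seeded stream."""
        if n_basis < 1 or r_max <= r_min or scale < 0 or cutoff <= r_max:
            raise InvalidParameterError("invalid surrogate basis parameters")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5752]))
        centers = np.linspace(r_min, r_max, n_basis)
        width = (r_max - r_min) / max(n_basis - 1, 1)
        weights = rng.normal(0.0, scale, size=n_basis)
        return cls(seed=seed, centers=tuple(centers),
                   widths=tuple([width] * n_basis), weights=tuple(weights),
                   cutoff=cutoff)


def surrogate_energy(lig_coords: np.ndarray, params: SurrogateParams,
                     with_gradient: bool = True):
    """Surrogate internal energy of one ligand.

    ``lig_coords`` has shape ``(..., m, 3)``; the result depends only on the
    intra-ligand pairwise distances, hence is exactly invariant to rigid
    translations and rotations.  A single bead has no internal coordinates
    and gets zero energy.
    """
    lig = np.asarray(lig_coords, dtype=float)
    if not np.all(np.isfinite(lig)):
        raise InvalidParameterError("ligand coordinates must be finite")
    m = lig.shape[-2]
    energy = np.zeros(lig.shape[:-2], dtype=float)
    grad = np.zeros_like(lig) if with_gradient else None
    if m < 2:
        return energy, grad
    centers = np.asarray(params.centers)
    widths = np.asarray(params.widths)
    weights = np.asarray(params.weights)
    for i in range(m):
        for j in range(i + 1, m):
            rij = lig[..., j, :] - lig[..., i, :]
            r = np.sqrt(np.sum(rij * rij, axis=-1))
            gauss = weights * np.exp(
                -0.5 * ((r[..., None] - centers) / widths) ** 2)
            e_pair = np.sum(gauss, axis=-1)
            # C1 switch from 1 to 0 over [cutoff - switch_width, cutoff]
            t = (r - (params.cutoff - params.switch_width)) / params.switch_width
            t = np.clip(t, 0.0, 1.0)
            s = 0.5 * (1.0 + np.cos(np.pi * t))
            energy = energy + e_pair * s
            if grad is not None:
                dpair_dr = np.sum(
                    gauss * (-(r[..., None] - centers) / widths ** 2), axis=-1)
                ds_dr = np.where((t > 0.0) & (t < 1.0),
                                 -0.5 * np.pi * np.sin(np.pi * t)
                                 / params.switch_width, 0.0)
                dedr = dpair_dr * s + e_pair * ds_dr
                with np.errstate(invalid="ignore", divide="ignore"):
                    unit = rij / np.maximum(r, 1e-300)[..., None]
                g = dedr[..., None] * unit
                grad[..., j, :] += g
                grad[..., i, :] -= g
    return energy, grad


# --------------------------------------------------------------------------
# hybrid decomposition
# --------------------------------------------------------------------------

def classify_terms(terms: Iterable[PotentialTerm], ligand_a: Sequence[int],
                   ligand_b: Sequence[int]):
    """Split terms into (environment, ligand-environment, intra-A, intra-B).

    A term is ligand-intramolecular iff *all* its participants lie in one
    ligand group and it is not an external-field term: tethers encode the
    host/solvent and stay on the MM side in hybrid mode.  A term touching
    both ligand groups has no well-defined owner under mechanical embedding
    and raises :class:`ClassificationError`.
    """
    set_a, set_b = frozenset(ligand_a), frozenset(ligand_b)
    if set_a & set_b:
        raise ClassificationError("ligand index groups overlap")
    env, lig_env, intra_a, intra_b = [], [], [], []
    for term in terms:
        parts = frozenset(term.participants)
        in_a, in_b = bool(parts & set_a), bool(parts & set_b)
        if in_a and in_b:
            raise ClassificationError(
                f"term {term} spans both ligand groups")
        if term.external_field:
            if in_a or in_b:
                lig_env.append(term)
            else:
                env.append(term)
        elif parts <= set_a:
            intra_a.append(term)
        elif parts <= set_b:
            intra_b.append(term)
        elif in_a or in_b:
            lig_env.append(term)
        else:
            env.append(term)
    return env, lig_env, intra_a, intra_b


@dataclass
class EnergyResult:
    """Energy, gradient and a per-component breakdown (kcal/mol)."""

    energy: np.ndarray
    gradient: np.ndarray | None
    components: dict = field(default_factory=dict)

    def format_components(self) -> str:
        """Plain-text component dump for debugging."""
        lines = []
        for key, val in self.components.items():
            v = float(np.asarray(val).reshape(-1)[0])
            lines.append(f"{key:>18s} : {v: .6f} kcal/mol")
        return "\n".join(lines)


def hybrid_energy(coords: np.ndarray, system: "ToySystem",
                  mode: str = "mm",
                  surrogates: dict | SurrogateParams | None = None,
                  with_gradient: bool = True) -> EnergyResult:
    """Evaluate the system in plain MM or hybrid (surrogate/MM) mode.

    In hybrid mode each ligand's intramolecular MM terms are replaced by
    :func:`surrogate_energy` of that ligand, leaving all ligand-environment
    and environment terms exactly as in MM.  ``surrogates`` may be a single
    :class:`SurrogateParams` (shared by both ligands) or a mapping with keys
    ``"A"`` and ``"B"``.
    """
    if mode not in ("mm", "hybrid"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    coords = np.asarray(coords, dtype=float)
    env, lig_env, intra_a, intra_b = classify_terms(
        system.potential_terms, system.ligand_a, system.ligand_b)

    e_env, g = mm_energy(coords, env, with_gradient=with_gradient)
    grad = g if with_gradient else None
    e_ligenv, g = mm_energy(coords, lig_env, with_gradient=with_gradient)
    if with_gradient:
        grad = grad + g
    components = {"environment": e_env, "ligand_environment": e_ligenv}
    energy = e_env + e_ligenv

    if mode == "mm":
        for label, intra in (("A", intra_a), ("B", intra_b)):
            e_i, g = mm_energy(coords, intra, with_gradient=with_gradient)
            components[f"intra_{label}_mm"] = e_i
            energy = energy + e_i
            if with_gradient:
                grad = grad + g
        return EnergyResult(energy, grad, components)

    if surrogates is None:
        raise InvalidParameterError("hybrid mode requires surrogate parameters")
    if isinstance(surrogates, SurrogateParams):
        surrogates = {"A": surrogates, "B": surrogates}
    for label, idx in (("A", system.ligand_a), ("B", system.ligand_b)):
        idx = np.asarray(idx, dtype=int)
        e_s, g_s = surrogate_energy(coords[..., idx, :], surrogates[label],
                                    with_gradient=with_gradient)
        components[f"intra_{label}_surrogate"] = e_s
        energy = energy + e_s
        if with_gradient:
            scatter = np.zeros_like(coords)
            scatter[..., idx, :] = g_s
            grad = grad + scatter
    return EnergyResult(energy, grad, components)
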