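"""Seeded generators of toy host-guest systems and synthetic edge networks.

These stand in for protein-ligand benchmark sets at desk scale: a "ligand"
is a group of 1-4 beads, the "host" is a pair of harmonic wells (binding
site and bulk) plus, optionally, a small Lennard-Jones cavity.  The
harmonic generator has a closed-form relative transfer free energy, which
makes it the end-to-end oracle for the whole alchemical pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KB, temperature_for_kt, thermal_energy
from .energy import (DualWellTether, HarmonicBond, HarmonicTether,
                     LennardJonesPair, PotentialTerm, TorsionCosine,
                     term_from_dict)
from .errors import InvalidParameterError

__all__ = [
    "ToySystem", "EdgeSet", "make_harmonic_host_guest",
    "analytic_transfer_ddg", "make_lj_ligand_system", "make_edge_network",
]

#: Default separation between site and bulk wells (angstrom).
DEFAULT_SEPARATION = 20.0

#: Default bead mass (amu); light enough to thermalize fast, heavy enough
#: for a 4 fs step on the stiffest default well.
DEFAULT_MASS = 12.0


@dataclass
class ToySystem:
    """A small particle system with ATM geometric annotations.

    The displacement vector (bulk_center - site_center) defines the
    coordinate swap that transfers ligand A from the binding site to the
    bulk while ligand B makes the reverse trip.
    """

    coordinates: np.ndarray            # (N, 3) angstrom
    potential_terms: list[PotentialTerm]
    ligand_a: tuple[int, ...]
    ligand_b: tuple[int, ...]
    site_center: np.ndarray            # (3,) angstrom
    bulk_center: np.ndarray            # (3,) angstrom
    temperature: float                 # Kelvin
    masses: np.ndarray | None = None   # (N,) amu
    analytic_ddg: float | None = None  # kcal/mol, when known in closed form
    label: str = "toy"

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise InvalidParameterError("coordinates must have shape (N, 3)")
        n = self.coordinates.shape[0]
        self.site_center = np.asarray(self.site_center, dtype=float)
        self.bulk_center = np.asarray(self.bulk_center, dtype=float)
        self.ligand_a = tuple(int(i) for i in self.ligand_a)
        self.ligand_b = tuple(int(i) for i in self.ligand_b)
        if set(self.ligand_a) & set(self.ligand_b):
            raise InvalidParameterError("ligand index groups must be disjoint")
        for idx in (*self.ligand_a, *self.ligand_b):
            if not (0 <= idx < n):
                raise InvalidParameterError(f"ligand index {idx} out of range")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive")
        if self.masses is None:
            self.masses = np.full(n, DEFAULT_MASS)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise InvalidParameterError("masses must be positive, one per particle")
        if self.analytic_ddg is not None and not math.isfinite(self.analytic_ddg):
            raise InvalidParameterError("analytic_ddg must be finite when set")

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[0]

    @property
    def displacement(self) -> np.ndarray:
        """bulk_center - site_center, the ATM transfer vector."""
        return self.bulk_center - self.site_center

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)

    @property
    def environment_indices(self) -> tuple[int, ...]:
        lig = set(self.ligand_a) | set(self.ligand_b)
        return tuple(i for i in range(self.n_particles) if i not in lig)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "temperature": float(self.temperature),
            "site_center": [float(v) for v in self.site_center],
            "bulk_center": [float(v) for v in self.bulk_center],
            "ligand_a": list(self.ligand_a),
            "ligand_b": list(self.ligand_b),
            "masses": [float(m) for m in self.masses],
            "coordinates": [[float(v) for v in row] for row in self.coordinates],
            "potential_terms": [t.to_dict() for t in self.potential_terms],
            "analytic_ddg": None if self.analytic_ddg is None
            else float(self.analytic_ddg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToySystem":
        return cls(
            coordinates=np.asarray(d["coordinates"], dtype=float),
            potential_terms=[term_from_dict(t) for t in d["potential_terms"]],
            ligand_a=tuple(d["ligand_a"]),
            ligand_b=tuple(d["ligand_b"]),
            site_center=np.asarray(d["site_center"], dtype=float),
            bulk_center=np.asarray(d["bulk_center"], dtype=float),
            temperature=float(d["temperature"]),
            masses=np.asarray(d["masses"], dtype=float),
            analytic_ddg=d.get("analytic_ddg"),
            label=d.get("label", "toy"),
        )


def analytic_transfer_ddg(k_site_a: float, k_bulk_a: float, k_site_b: float,
                          k_bulk_b: float, kT: float = 1.0) -> float:
    """Closed-form relative transfer free energy of two 3D harmonic ligands.

    Each ligand is a single bead in a 3D harmonic well with partition
    function Z(k) = (2 pi kT / k)^(3/2).  Swapping A (site -> bulk) with B
    (bulk -> site) gives

        ddG = (3/2) kT [ ln(k_bulk_A / k_site_A) - ln(k_bulk_B / k_site_B) ]

    in kcal/mol when kT is.  Antisymmetric under exchanging the A and B
    labels, and zero when the two ligands are identical.
    """
    for name, k in (("k_site_a", k_site_a), ("k_bulk_a", k_bulk_a),
                    ("k_site_b", k_site_b), ("k_bulk_b", k_bulk_b),
                    ("kT", kT)):
        if k <= 0:
            raise InvalidParameterError(f"{name} must be positive")
    return 1.5 * kT * (math.log(k_bulk_a / k_site_a)
                       - math.log(k_bulk_b / k_site_b))


def make_harmonic_host_guest(k_site: float = 4.0, k_bulk: float = 1.0,
                             k_site_b: float = 1.0, k_bulk_b: float = 1.0,
                             temperature: float | None = None,
                             kT: float | None = None,
                             separation: float = DEFAULT_SEPARATION,
                             ) -> ToySystem:
    """Two single-bead ligands in dual harmonic wells, with exact ddG.

    Ligand A starts bound (site well, spring ``k_site``) and ligand B
    solvated (bulk well, spring ``k_bulk_b``); ``k_bulk`` and ``k_site_b``
    are the springs each would feel after the transfer.  The analytic ddG
    is stored on the returned system.  Specify the thermodynamic state
    either as ``temperature`` (K) or as ``kT`` (kcal/mol); default kT = 1.
    """
    for name, k in (("k_site", k_site), ("k_bulk", k_bulk),
                    ("k_site_b", k_site_b), ("k_bulk_b", k_bulk_b)):
        if k <= 0:
            raise InvalidParameterError(f"{name} must be positive")
    if separation <= 0:
        raise InvalidParameterError("separation must be positive")
    if temperature is None:
        temperature = temperature_for_kt(1.0 if kT is None else kT)
    elif kT is not None:
        raise InvalidParameterError("give either temperature or kT, not both")
    site = np.zeros(3)
    bulk = np.array([separation, 0.0, 0.0])
    terms: list[PotentialTerm] = [
        DualWellTether(0, k_site=k_site, k_bulk=k_bulk,
                       site_center=tuple(site), bulk_center=tuple(bulk)),
        DualWellTether(1, k_site=k_site_b, k_bulk=k_bulk_b,
                       site_center=tuple(site), bulk_center=tuple(bulk)),
    ]
    ddg = analytic_transfer_ddg(k_site, k_bulk, k_site_b, k_bulk_b,
                                kT=KB * temperature)
    return ToySystem(
        coordinates=np.stack([site, bulk]),
        potential_terms=terms,
        ligand_a=(0,), ligand_b=(1,),
        site_center=site, bulk_center=bulk,
        temperature=temperature,
        analytic_ddg=ddg,
        label="harmonic_host_guest",
    )


def make_lj_ligand_system(n_beads_a: int = 3, n_beads_b: int = 2,
                          seed: int = 0,
                          temperature: float | None = None) -> ToySystem:
    """A non-analytic stress-test system: bead-chain ligands in an LJ cavity.

    Each ligand is a 1-4 bead chain with harmonic bonds (and a cosine
    torsion when it has four beads), anchored in its basin by dual-well
    tethers; four environment beads tethered around the binding site
    interact with every ligand bead through Lennard-Jones pairs.  No closed
    form exists for its transfer free energy, which is the point: it
    exercises every term kind and the full hybrid decomposition.
    Deterministic for a fixed seed.
    """
    for name, nb in (("n_beads_a", n_beads_a), ("n_beads_b", n_beads_b)):
        if not (1 <= nb <= 4):
            raise InvalidParameterError(f"{name} must be between 1 and 4")
    if temperature is None:
        temperature = temperature_for_kt(0.596)  # ~300 K
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11A9]))
    site = np.zeros(3)
    bulk = np.array([DEFAULT_SEPARATION, 0.0, 0.0])

    # four cavity beads around the site, strongly tethered
    cavity_dirs = np.array([[1.0, 1.0, 1.0], [-1.0, -1.0, 1.0],
                            [-1.0, 1.0, -1.0], [1.0, -1.0, -1.0]])
    cavity_dirs /= np.linalg.norm(cavity_dirs, axis=1, keepdims=True)
    cavity = site + 4.5 * cavity_dirs

    coords = []
    terms: list[PotentialTerm] = []
    bond_r0, bond_k = 1.5, 100.0

    def add_ligand(n_beads: int, anchor: np.ndarray) -> tuple[int, ...]:
        start = len(coords)
        offsets = np.arange(n_beads) - 0.5 * (n_beads - 1)
        for m in range(n_beads):
            pos = anchor + np.array([0.0, offsets[m] * bond_r0, 0.0])
            pos = pos + rng.uniform(-0.2, 0.2, size=3)
            coords.append(pos)
        idx = tuple(range(start, start + n_beads))
        for m in range(n_beads - 1):
            terms.append(HarmonicBond(idx[m], idx[m + 1], k=bond_k, r0=bond_r0))
        if n_beads == 4:
            terms.append(TorsionCosine(*idx, amplitude=1.2, periodicity=3))
        for i in idx:
            terms.append(DualWellTether(i, k_site=1.0, k_bulk=1.0,
                                        site_center=tuple(site),
                                        bulk_center=tuple(bulk)))
        return idx

    lig_a = add_ligand(n_beads_a, site)
    lig_b = add_ligand(n_beads_b, bulk)
    env_start = len(coords)
    coords.extend(cavity)
    env_idx = range(env_start, env_start + len(cavity))
    for e in env_idx:
        terms.append(HarmonicTether(e, center=tuple(coords[e]), k=50.0))
        for i in (*lig_a, *lig_b):
            terms.append(LennardJonesPair(i, e, epsilon=0.15, sigma=2.5))

    return ToySystem(
        coordinates=np.asarray(coords),
        potential_terms=terms,
        ligand_a=lig_a, ligand_b=lig_b,
        site_center=site, bulk_center=bulk,
        temperature=temperature,
        label=f"lj_ligand_{n_beads_a}x{n_beads_b}_seed{seed}",
    )


# --------------------------------------------------------------------------
# synthetic perturbation-edge networks
# --------------------------------------------------------------------------

@dataclass
class EdgeSet:
    """A synthetic ligand-pair ddG table with known generating truth.

    Edges follow the convention ddg(i -> j) = dG_j - dG_i.  ``true_dgs``
    records the per-ligand free energies used to generate the edges;
    ``ddg_exp`` columns are the exact (noise-free) differences.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float, float, float]]  # i, j, calc, sigma, exp
    true_dgs: dict[str, float] = field(default_factory=dict)
    underconnected: bool = False

    def __post_init__(self):
        seen = set()
        for (i, j, _calc, sigma, _exp) in self.edges:
            if i == j:
                raise InvalidParameterError(f"self edge on node {i}")
            if sigma <= 0:
                raise InvalidParameterError(f"edge {i}-{j} has sigma <= 0")
            key = frozenset((i, j))
            if key in seen:
                raise InvalidParameterError(f"duplicate pair {i}-{j}")
            seen.add(key)


def make_edge_network(n_ligands: int = 10, edge_fraction: float = 1.0,
                      noise_sigma: float = 0.3, seed: int = 0,
                      dg_spread: float = 1.5) -> EdgeSet:
    """Draw a synthetic ddG perturbation network with Gaussian edge noise.

    Per-ligand true free energies are N(0, dg_spread^2); a fraction of all
    unordered pairs is kept (sampled without replacement), and each kept
    edge reports ddg_calc = (dG_j - dG_i) + N(0, noise_sigma^2) with
    ddg_exp the exact difference.  If fewer than n_ligands - 1 edges
    survive, the set is flagged ``underconnected``.
    """
    if n_ligands < 2:
        raise InvalidParameterError("need at least two ligands")
    if not (0.0 <= edge_fraction <= 1.0):
        raise InvalidParameterError("edge_fraction must lie in [0, 1]")
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xED6E]))
    width = len(str(n_ligands - 1))
    nodes = [f"L{i:0{width}d}" for i in range(n_ligands)]
    true = rng.normal(0.0, dg_spread, size=n_ligands)
    pairs = [(i, j) for i in range(n_ligands) for j in range(i + 1, n_ligands)]
    n_keep = int(round(edge_fraction * len(pairs)))
    keep = sorted(rng.choice(len(pairs), size=n_keep, replace=False))
    sigma = max(noise_sigma, 1e-9)  # edge sigmas must stay positive
    edges = []
    for idx in keep:
        i, j = pairs[idx]
        exact = true[j] - true[i]
        noisy = exact + (rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0)
        edges.append((nodes[i], nodes[j], float(noisy), sigma, float(exact)))
    return EdgeSet(
        nodes=nodes,
        edges=edges,
        true_dgs={nodes[i]: float(true[i]) for i in range(n_ligands)},
        underconnected=len(edges) < n_ligands - 1,
    )
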