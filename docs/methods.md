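# Methods

This note records what atmkit actually computes, the assumptions behind
each stage, the defaults that matter, and what the toy validation does and
does not demonstrate about production RBFE calculations.

## Units and conventions

Energies are kcal/mol, lengths Å, masses amu, times ps, temperatures
Kelvin, with k_B = 0.0019872041 kcal/mol/K; 1 kcal/mol = 418.4 amu·Å²/ps²
exactly, which is the only conversion the dynamics needs.  Atom indices
are 0-based in the API and in every file format.  Edge files follow the
convention ΔΔG(i→j) = ΔG_j − ΔG_i.  Most toy work is done in natural
units kT = 1 kcal/mol (T ≈ 503.2 K); generators accept either `kT` or
`temperature`.

## Toy systems

A "ligand" is a group of 1–4 beads, not an all-atom molecule, so that
every statistical claim is testable on one CPU in seconds.  The host is a
**dual-well tether**: each ligand particle feels the lower of two harmonic
wells, one at the binding-site center and one at the bulk center (default
separation 20 Å).  With deep, well-separated wells each basin is an exact
3D harmonic well, so basin partition functions — and hence the transfer
free energy

ΔΔG = (3/2)·kT·[ln(k_bulk_A/k_site_A) − ln(k_bulk_B/k_site_B)]

— are available in closed form; a numerical-quadrature oracle confirms the
formula to < 1e-6 kcal/mol in the tests.  The nearest-well selection makes
the gradient discontinuous on the equal-energy midplane, a measure-zero
surface ~50 kT uphill at the defaults and never sampled; finite-difference
gradient checks stay away from it.  The mid-basin barrier also provides
the kinetic confinement that ATM endpoint ensembles rely on: each leg
samples one basin, and the estimated ΔΔG is the basin-restricted free
energy difference the closed form describes.

The non-analytic stress-test system adds harmonic-bond bead chains (a
cosine torsion at four beads), a Lennard-Jones cavity of four strongly
tethered environment beads, and dual-well anchors; it exercises every term
kind and the full hybrid decomposition where no closed form exists.

Synthetic ΔΔG networks draw per-ligand true free energies from N(0,
1.5²) kcal/mol, keep a chosen fraction of all unordered pairs, and add
Gaussian noise of a chosen σ to each edge; the exact differences are kept
as the "experimental" column and the generating values are retained for
recovery tests.  Defaults (10 ligands, complete graph, σ = 0.3 kcal/mol)
give per-edge noise comparable to a well-converged calculation; the
proportion of pairs retained is exposed as a parameter because a sparse,
randomly chosen subset is exactly what degrades network connectivity in
practice.

## Hybrid surrogate/MM energies

Hybrid mode implements mechanical embedding: for each ligand, every MM
term whose participants all lie inside that ligand's index group is
removed and replaced by a surrogate energy of the ligand's internal
geometry.  Two deliberate choices:

- **Tethers are never intramolecular.**  Position-anchored terms encode
  the host/solvent field, so they stay on the MM side even when their
  particle belongs to a ligand.  This preserves the identity that
  single-bead ligands make hybrid and MM modes exactly equal.
- **Terms spanning both ligands are an error.**  Under mechanical
  embedding such a term has no owner; the classifier refuses rather than
  guessing.

The surrogate itself is a weighted sum of Gaussian radial basis functions
over intra-ligand pairwise distances (8 bases on 0.8–6 Å, weights drawn
once from a seeded stream, C¹ cosine switch at 8 Å).  It is not trained
and does not approximate any specific potential; it reproduces the
*contract* of a learned intramolecular potential — smooth, exactly
invariant to rigid motion, analytic gradient — which is what the
alchemical machinery depends on.  Electrostatic embedding (polarizing the
ligand by environment charges) is out of scope; ligand–environment
electrostatics, where present, are plain MM point-charge terms in both
modes.

## Alchemical path

The perturbation energy u(x) = E(swap(x)) − E(x) is the single collective
variable.  The swap translates each ligand toward the *opposite* center
(direction decided by the ligand centroid), which makes the transform an
involution — applying it to an already-swapped configuration undoes the
transfer — exact to the floating-point roundoff of a ±20 Å translation
(~1e-15 Å relative); u is antisymmetric under it by construction.

The soft-core cap uses the rational form u_sc = u_c + (u_max − u_c)·f(y),
f(y) = (z^{1/a} − 1)/(z^{1/a} + 1), z = 1 + 2ay + 2(ay)²,
y = (u − u_c)/(u_max − u_c), chosen because it is the identity below u_c,
has exactly unit slope at the joint (C¹), is strictly monotone, and
saturates at u_max.  Defaults u_max = 200, u_c = 100 kcal/mol, a = 1/16.
In the harmonic toys |u| stays far below u_c, so both legs see the
identity branch and the two legs' λ = ½ ensembles coincide exactly.

The softplus bias W_λ(u_sc) = λ₂·u_sc + ((λ₂ − λ₁)/α)·ln[1 +
exp(−α(u_sc − u₀))] + w₀ has slope λ₁·s + λ₂·(1−s) with
s = sigmoid(−α(u_sc − u₀)): it interpolates between coupling λ₁ for very
favorable u and λ₂ for very unfavorable u, is monotone whenever λ₁, λ₂ ≥
0, and collapses to the linear coupling λ·u_sc + w₀ when λ₁ = λ₂ (computed
on that exact branch, not by cancellation).  α = 0 with λ₁ ≠ λ₂ has no
defined limit and is rejected.  Defaults: α = 0.1 (kcal/mol)⁻¹, u₀ = 110,
w₀ = 0.

Schedules place λ evenly on [0, ½] (default 11 windows per leg; both legs
share the grid and differ only in the direction flag).  The `linear`
family sets λ₁ = λ₂ = λ; the `softplus` family ramps λ₂ = 2λ² under
λ₁ = λ so the two meet at the midpoint.  The linear family is the default
because the toy systems have no endpoint singularity for the softplus
shape to tame.

## Sampling

Dynamics is BAOAB-splitting Langevin.  Defaults: 4 fs timestep in MM mode,
1 fs in hybrid mode (bead masses of 12 amu keep both stable: the stiffest
default well has ω·dt ≈ 0.05), friction 1/ps.  Exchange is synchronous
neighbor swap with even/odd pair alternation — simpler to test than an
asynchronous scheme and with the same stationary distribution; the swap of
states i, j is accepted with probability min(1, exp(−[W_i(u_j) + W_j(u_i)
− W_i(u_i) − W_j(u_j)]/kT)) on soft-core-capped perturbation energies.

One leg runs: anneal from λ = 0 to ½ (the annealed configuration seeds
every window), equilibrate with unrecorded dynamics + exchanges, then
alternate dynamics and sweeps while recording u per window.  Replicates
(default 3) use disjoint named substreams of the run seed; everything —
including exchange decisions — replays bit-identically under a fixed seed.

Desk-scale budgets: the default RunSpec (11 windows × 20,000 steps,
exchange and sampling every 250 steps, 2,500 anneal + 2,500 equilibration
steps) takes seconds per leg on one CPU.  The validation suite and the
acceptance script raise friction to 10/ps so that positions decorrelate in
~0.2 ps and samples taken 1 ps apart are effectively independent — the
assumption under which the UWHAM error bar is honest.  At the default
friction of 1/ps the same stride leaves mild correlation and the reported
σ underestimates modestly; stride-based subsampling is available on
`PerturbationSamples.subsampled` for that regime.

## UWHAM estimation

The solver runs stabilized log-sum-exp self-consistent iteration on the
reduced free energies (gauge f₁ = 0), switching to direct L-BFGS
minimization of the multistate negative log-likelihood if the residual
stalls, and refuses (with the last residual attached) rather than return
an unconverged answer.  Zero-count "virtual" windows are allowed and
reduce to the one-sided exponential-average estimate.  The estimate is
invariant to per-sample column shifts and equivariant to per-state row
shifts of the bias matrix, both exactly.

Uncertainties are the estimator's asymptotic covariance, computed via an
SVD of the normalized weight matrix; over 200 independent two-state
Gaussian repetitions the 2σ interval covers the truth in ≈95% of runs
(checked in the acceptance tests).  ΔΔG = ΔG_leg1 − ΔG_leg2 with σ
combined in quadrature; across replicates the reported value is the plain
mean with the standard error of the mean (each replicate's internal σ is
then ignored — with 3 replicates the SEM itself carries ~50% relative
error, which is why single-replicate runs with honest asymptotic σ are
used where a tight interval matters).

## Network maximum likelihood

Per connected component, node free energies minimize Σ (ΔΔG_ij − (g_j −
g_i))²/σ_ij² and are obtained from the pseudo-inverse of the weighted
graph Laplacian, which lands on the zero-mean gauge; node σ are the square
roots of the pseudo-inverse diagonal.  Estimates are never compared across
components — a disconnected network yields groups whose offsets are
mutually unknown — and experiment anchoring shifts each component so the
mean over its experimentally annotated nodes matches the experimental
mean (idempotent; σ unchanged; components with no anchor are left in the
zero-mean gauge with a warning).  Anchoring to a single reference ligand
is a degenerate case of the same operation (one annotated node).

## Benchmark statistics

MAE, RMSE and Kendall τ-b (tie-corrected; ranks only, so invariant to
monotone transforms) with pair-bootstrap uncertainties (default 1,000
resamples; resamples where τ is undefined are skipped and counted), plus
the fraction of pairs within fixed thresholds (defaults 1.0 and 1.5
kcal/mol).  Method-comparison tables refuse edge sets that differ between
methods, since the statistics would not be comparable.  Pearson
correlation is deliberately excluded from default reports: on ΔΔG edges
it depends on which ligand pairs happened to be computed.

## Numerical choices and degenerate inputs

- Double precision throughout the alchemical path; log-sum-exp for every
  softplus and UWHAM denominator; the soft-core saturates to u_max within
  one ulp for very large u (monotone up to roundoff).
- Coincident particles in LJ/Coulomb pairs raise a singular-geometry
  error instead of returning inf.
- Edge σ must be positive everywhere (files and API); the noise-free
  synthetic generator emits σ = 1e-9 kcal/mol as an exact-data marker.
- CSV round-trips use `repr` floats, so written and re-read values are
  bit-identical.

## What the toy validation shows — and what it does not

Passing tests demonstrate that the estimation machinery is correct: the
alchemical path, exchange kernel, multistate estimator, its error bar,
the network solver and the statistics layer all agree with closed forms,
independent oracles and brute force on systems where truth is known.
They do not demonstrate force-field accuracy, sampling adequacy for
rugged all-atom landscapes, conformational trapping behavior, finite-size
or electrostatic artifacts, or NNP fidelity — the toy surrogate is
deliberately not a model of any real intramolecular surface.  Results on
bead systems transfer to production work only at the level of the
statistical pipeline, which is precisely the component this package
isolates.
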