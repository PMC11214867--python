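"""Unbinned weighted-histogram (UWHAM/MBAR-type) free-energy estimation.

Given samples cross-evaluated at every lambda window -- the reduced bias
matrix b_kn = W_k(u_n)/kT -- the estimator solves the self-consistent
equations

    f_k = -ln sum_n exp(-b_kn) / sum_l N_l exp(f_l - b_ln)

for the per-window reduced free energies (gauge f_1 = 0), which is the
maximum-likelihood multistate reweighting solution.  The window-to-window
free energy is ΔG = kT (f_K - f_1), with its uncertainty from the
estimator's asymptotic covariance computed on the normalized sample
weight matrix.

Samples from a window are treated as independent; the sampling defaults
space them about one position-decorrelation time apart.  Optional
stride-based subsampling is available for strongly correlated series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import ConvergenceError, InvalidInputError

__all__ = ["PerturbationSamples", "FreeEnergyResult", "uwham_solve",
           "ddg_from_legs", "combine_replicates"]


@dataclass
class PerturbationSamples:
    """Cross-evaluated reduced bias energies consumed by UWHAM.

    ``bias_matrix`` has shape (K, N): row k holds W_k(u_n)/kT for every
    sample n (all windows pooled, state-major order); ``sample_counts``
    says how many of the N samples came from each window.  A zero count
    marks a "virtual" window that contributed no samples but is still
    reweighted to (the Zwanzig single-state limit).
    """

    bias_matrix: np.ndarray
    sample_counts: np.ndarray
    lambdas: np.ndarray | None = None
    leg: int = 1
    replicate: int = 0
    kT: float = 1.0
    u_series: np.ndarray | None = None            # (K, n_samples) raw u
    exchange_acceptance: np.ndarray | None = None

    def __post_init__(self):
        self.bias_matrix = np.asarray(self.bias_matrix, dtype=float)
        self.sample_counts = np.asarray(self.sample_counts, dtype=int)
        if self.bias_matrix.ndim != 2:
            raise InvalidInputError("bias_matrix must be 2D (states x samples)")
        k, n = self.bias_matrix.shape
        if self.sample_counts.shape != (k,):
            raise InvalidInputError("need one sample count per state")
        if np.any(self.sample_counts < 0) or self.sample_counts.sum() != n:
            raise InvalidInputError(
                "sample counts must be non-negative and sum to the sample axis")
        if self.sample_counts.sum() == 0:
            raise InvalidInputError("no samples at all")
        if not np.all(np.isfinite(self.bias_matrix)):
            raise InvalidInputError("bias matrix must be finite")

    def subsampled(self, stride: int) -> "PerturbationSamples":
        """Thin each window's series by ``stride`` (correlation control)."""
        if stride < 1:
            raise InvalidInputError("stride must be >= 1")
        if stride == 1:
            return self
        keep = []
        offset = 0
        new_counts = []
        for c in self.sample_counts:
            idx = np.arange(offset, offset + c, stride)
            keep.append(idx)
            new_counts.append(len(idx))
            offset += c
        keep = np.concatenate(keep)
        return PerturbationSamples(
            bias_matrix=self.bias_matrix[:, keep],
            sample_counts=np.asarray(new_counts), lambdas=self.lambdas,
            leg=self.leg, replicate=self.replicate, kT=self.kT)


@dataclass
class FreeEnergyResult:
    """Per-window reduced free energies and the end-to-end ΔG ± σ."""

    f: np.ndarray                 # (K,), reduced, f[0] == 0
    delta_g: float                # kcal/mol, kT * (f[-1] - f[0])
    sigma: float                  # kcal/mol
    iterations: int
    residual: float
    converged: bool
    kT: float = 1.0
    covariance: np.ndarray | None = field(default=None, repr=False)


def _log_denominator(f, bias, log_counts, active):
    # log sum_l N_l exp(f_l - b_ln), over states with samples
    return logsumexp(f[active, None] - bias[active, :]
                     + log_counts[:, None], axis=0)


def _neg_log_likelihood(f, bias, counts, log_counts, active):
    log_den = _log_denominator(f, bias, log_counts, active)
    return float(np.sum(log_den) - np.dot(counts[active], f[active]))


def uwham_solve(samples: PerturbationSamples, tol: float = 1e-10,
                max_iter: int = 10000) -> FreeEnergyResult:
    """Solve the UWHAM self-consistent equations.

    Stabilized log-sum-exp self-consistent iteration with a direct
    likelihood-minimization fallback if the residual stalls; raises
    :class:`ConvergenceError` (carrying the last residual) if neither
    reaches ``tol`` within ``max_iter``.  The error bar on ΔG comes from
    the asymptotic covariance of the maximum-likelihood estimator,
    evaluated through an SVD of the normalized weight matrix.
    """
    bias = samples.bias_matrix
    counts = samples.sample_counts.astype(float)
    k, n = bias.shape
    if k < 2:
        raise InvalidInputError("need at least two states")
    active = counts > 0
    log_counts = np.log(counts[active])

    f = np.zeros(k)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        log_den = _log_denominator(f, bias, log_counts, active)
        f_new = -logsumexp(-bias - log_den[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
        if it == 200 and residual > 1e-4:
            # slow self-consistency: descend on the likelihood directly
            free = slice(1, k)

            def objective(x):
                ff = np.concatenate(([0.0], x))
                return _neg_log_likelihood(ff, bias, counts, log_counts,
                                           active)

            res = minimize(objective, f[free], method="L-BFGS-B",
                           options={"maxiter": max_iter, "ftol": 1e-15,
                                    "gtol": 1e-12})
            f = np.concatenate(([0.0], res.x))
    converged = residual < tol
    if not converged:
        raise ConvergenceError(
            f"UWHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})", residual=residual)

    # normalized weights W_nk = exp(f_k - b_kn) / sum_l N_l exp(f_l - b_ln)
    log_den = _log_denominator(f, bias, log_counts, active)
    w = np.exp((f[:, None] - bias - log_den[None, :]).T)   # (N, K)
    # asymptotic covariance Theta = V S (I - S V' N V S)^+ S V'
    _, s_svd, vt = np.linalg.svd(w, full_matrices=False)
    v = vt.T
    s_mat = np.diag(s_svd)
    inner = np.eye(len(s_svd)) - s_mat @ vt @ np.diag(counts) @ v @ s_mat
    theta = v @ s_mat @ np.linalg.pinv(inner) @ s_mat @ vt
    var = theta[-1, -1] + theta[0, 0] - 2.0 * theta[0, -1]
    sigma = samples.kT * float(np.sqrt(max(var, 0.0)))
    delta_g = samples.kT * float(f[-1] - f[0])
    return FreeEnergyResult(f=f, delta_g=delta_g, sigma=sigma,
                            iterations=it, residual=residual,
                            converged=True, kT=samples.kT,
                            covariance=theta)


def ddg_from_legs(leg1: FreeEnergyResult,
                  leg2: FreeEnergyResult) -> tuple[float, float]:
    """ΔΔG = ΔG_leg1 - ΔG_leg2 with propagated uncertainty.

    Leg 1 climbs from the physical (bound-A) state to the symmetric
    intermediate and leg 2 from the swapped state, so their difference is
    the full transfer free energy.
    """
    for res in (leg1, leg2):
        if not res.converged:
            raise ConvergenceError("refusing ΔΔG from an unconverged leg")
    ddg = leg1.delta_g - leg2.delta_g
    sigma = float(np.hypot(leg1.sigma, leg2.sigma))
    return ddg, sigma


def combine_replicates(values: list[tuple[float, float]]
                       ) -> tuple[float, float]:
    """Mean ΔΔG across replicates with the standard error of the mean.

    With n >= 2 replicates the reported uncertainty is the SEM of the
    replicate means (each replicate's own estimator error is ignored); a
    single replicate passes through its own (value, sigma) unchanged.
    """
    if not values:
        raise InvalidInputError("no replicates to combine")
    if len(values) == 1:
        return float(values[0][0]), float(values[0][1])
    vals = np.array([v[0] for v in values], dtype=float)
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return mean, sem
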