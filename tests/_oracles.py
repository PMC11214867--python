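"""Independent reference implementations used only by the test suite.

Each oracle takes a deliberately different route from the package code it
checks: numerical quadrature instead of closed forms, derivative-free
likelihood minimization instead of self-consistent iteration, exhaustive
O(n^2) pair counting instead of library rank statistics, and dense
least squares instead of Laplacian pseudo-inverses.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.special import logsumexp


def quadrature_transfer_ddg(k_site_a, k_bulk_a, k_site_b, k_bulk_b, kT=1.0,
                            half_width=40.0):
    """ΔΔG for swapping two 3D harmonic ligands, by numerical quadrature.

    Each 3D well factorizes into three identical 1D Gaussian integrals
    Z1(k) = ∫ exp(-k x^2 / (2 kT)) dx, so ln Z = 3 ln Z1.  The transfer
    free energy is -kT ln of the swapped-to-physical partition ratio.
    """

    def log_z(k):
        val, _ = quad(lambda x: np.exp(-0.5 * k * x * x / kT),
                      -half_width, half_width, limit=200)
        return 3.0 * np.log(val)

    log_z_phys = log_z(k_site_a) + log_z(k_bulk_b)
    log_z_swap = log_z(k_bulk_a) + log_z(k_site_b)
    return -kT * (log_z_swap - log_z_phys)


def multistate_reweight(bias_matrix, sample_counts, kT=1.0):
    """Multistate reweighting free energies by direct minimization.

    Minimizes the pooled-sample negative log-likelihood
    sum_n ln sum_k N_k exp(f_k - b_kn) - sum_k N_k f_k over the reduced
    free energies (gauge f_0 = 0) with the derivative-free Nelder-Mead
    simplex, entirely independent of the package's self-consistent
    iteration.  Returns the reduced free energies.
    """
    bias = np.asarray(bias_matrix, dtype=float)
    counts = np.asarray(sample_counts, dtype=float)
    k = bias.shape[0]
    active = counts > 0
    log_counts = np.log(counts[active])

    def nll(free):
        f = np.concatenate(([0.0], free))
        log_den = logsumexp(f[active, None] - bias[active, :]
                            + log_counts[:, None], axis=0)
        return np.sum(log_den) - np.dot(counts[active], f[active])

    res = minimize(nll, np.zeros(k - 1), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12,
                            "maxiter": 40000, "maxfev": 40000})
    f = np.concatenate(([0.0], res.x))
    # virtual (zero-count) states do not enter the likelihood: fill them
    # with the explicit reweighting formula
    if not np.all(active):
        log_den = logsumexp(f[active, None] - bias[active, :]
                            + log_counts[:, None], axis=0)
        for idx in np.nonzero(~active)[0]:
            f[idx] = -logsumexp(-bias[idx] - log_den)
    return f


def kendall_tau_exhaustive(x, y):
    """Tie-corrected Kendall tau-b by explicit O(n^2) pair enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[j] - x[i])
            dy = np.sign(y[j] - y[i])
            if dx == 0:
                ties_x += 1
            if dy == 0:
                ties_y += 1
            if dx == 0 or dy == 0:
                continue
            if dx == dy:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt(float(n0 - ties_x) * float(n0 - ties_y))
    if denom == 0:
        raise ZeroDivisionError("tau undefined: one input all ties")
    return (concordant - discordant) / denom


def network_mle_leastsq(node_ids, edges):
    """Node free energies by dense weighted least squares (zero-mean gauge).

    ``edges`` is a list of (i, j, ddg, sigma) with ddg = g_j - g_i.  Builds
    the weighted design matrix row by row and solves with
    ``numpy.linalg.lstsq``, then centers -- no graph Laplacian involved.
    """
    index = {node: m for m, node in enumerate(node_ids)}
    rows, rhs = [], []
    for (i, j, ddg, sigma) in edges:
        row = np.zeros(len(node_ids))
        row[index[j]] = 1.0 / sigma
        row[index[i]] = -1.0 / sigma
        rows.append(row)
        rhs.append(ddg / sigma)
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    return sol - sol.mean()
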