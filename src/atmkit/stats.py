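"""Benchmark statistics for calculated vs experimental free energies.

The evaluation layer reports the mean absolute error (MAE), root-mean-square
error (RMSE) and Kendall tau-b rank correlation per method, each with a
pair-bootstrap uncertainty, plus the fraction of pairs predicted within
fixed kcal/mol thresholds.  Pearson correlation is deliberately not part of
the default report: on ΔΔG edges it depends on the (arbitrary) choice of
ligand pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, UndefinedCorrelationError

__all__ = ["BenchmarkStats", "BootstrapResult", "error_stats", "kendall_tau",
           "bootstrap_uncertainty", "fraction_within", "compute_benchmark",
           "method_comparison_table", "format_comparison_table"]

DEFAULT_THRESHOLDS = (1.0, 1.5)


def _validated(calc, exp, min_len=1):
    calc = np.asarray(calc, dtype=float).ravel()
    exp = np.asarray(exp, dtype=float).ravel()
    if calc.shape != exp.shape:
        raise InvalidInputError("calc and exp must have equal length")
    if calc.size < min_len:
        raise InvalidInputError(f"need at least {min_len} pairs")
    if not (np.all(np.isfinite(calc)) and np.all(np.isfinite(exp))):
        raise InvalidInputError("inputs must be finite")
    return calc, exp


def error_stats(calc, exp) -> tuple[float, float]:
    """(MAE, RMSE) in the units of the inputs.  MAE <= RMSE always."""
    calc, exp = _validated(calc, exp)
    err = calc - exp
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err * err)))


def kendall_tau(calc, exp) -> float:
    """Kendall tau-b (tie-corrected) rank correlation.

    Equals (concordant - discordant) / (n(n-1)/2) on tie-free data.
    Raises :class:`UndefinedCorrelationError` when either input is
    constant, where rank correlation has no meaning.
    """
    calc, exp = _validated(calc, exp, min_len=2)
    if np.all(calc == calc[0]) or np.all(exp == exp[0]):
        raise UndefinedCorrelationError(
            "Kendall tau undefined for constant input")
    tau = sps.kendalltau(calc, exp, variant="b").statistic
    return float(tau)


@dataclass(frozen=True)
class BootstrapResult:
    """A statistic with its pair-bootstrap standard deviation."""

    stat: float
    sigma: float
    n_skipped: int = 0  # degenerate resamples (e.g. all-tie tau)

    def __iter__(self):
        return iter((self.stat, self.sigma))


def bootstrap_uncertainty(stat_fn, calc, exp, n_boot: int = 1000,
                          seed: int = 0) -> BootstrapResult:
    """Pair bootstrap: resample ligand pairs with replacement.

    ``stat_fn(calc, exp) -> float`` is evaluated on each resample; the
    reported sigma is the standard deviation of the resampled statistic.
    Resamples where the statistic is undefined (all-tie rank correlation)
    are skipped and counted.  Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise InvalidInputError("n_boot must be >= 100")
    calc, exp = _validated(calc, exp)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
    stat = float(stat_fn(calc, exp))
    values = []
    skipped = 0
    n = calc.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(stat_fn(calc[idx], exp[idx])))
        except UndefinedCorrelationError:
            skipped += 1
    if not values:
        raise InvalidInputError("all bootstrap resamples were degenerate")
    return BootstrapResult(stat=stat, sigma=float(np.std(values)),
                           n_skipped=skipped)


def fraction_within(calc, exp, thresholds=DEFAULT_THRESHOLDS) -> dict:
    """Fraction of pairs with |calc - exp| below each threshold (kcal/mol)."""
    calc, exp = _validated(calc, exp)
    err = np.abs(calc - exp)
    out = {}
    for t in thresholds:
        if t <= 0:
            raise InvalidInputError("thresholds must be positive")
        out[float(t)] = float(np.mean(err < t))
    return out


@dataclass
class BenchmarkStats:
    """MAE/RMSE/tau with bootstrap uncertainties and threshold fractions."""

    n_pairs: int
    mae: float
    mae_sigma: float
    rmse: float
    rmse_sigma: float
    kendall_tau: float
    tau_sigma: float
    fraction_below: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mae > self.rmse + 1e-12:
            raise InvalidInputError("MAE cannot exceed RMSE")


def compute_benchmark(calc, exp, thresholds=DEFAULT_THRESHOLDS,
                      n_boot: int = 1000, seed: int = 0) -> BenchmarkStats:
    """Full statistics block for one method on one edge set."""
    calc, exp = _validated(calc, exp, min_len=2)
    mae_b = bootstrap_uncertainty(lambda c, e: error_stats(c, e)[0],
                                  calc, exp, n_boot, seed)
    rmse_b = bootstrap_uncertainty(lambda c, e: error_stats(c, e)[1],
                                   calc, exp, n_boot, seed)
    tau_b = bootstrap_uncertainty(kendall_tau, calc, exp, n_boot, seed)
    return BenchmarkStats(
        n_pairs=int(calc.size),
        mae=mae_b.stat, mae_sigma=mae_b.sigma,
        rmse=rmse_b.stat, rmse_sigma=rmse_b.sigma,
        kendall_tau=tau_b.stat, tau_sigma=tau_b.sigma,
        fraction_below=fraction_within(calc, exp, thresholds),
    )


def method_comparison_table(runs: dict[str, pd.DataFrame],
                            n_boot: int = 1000, seed: int = 0
                            ) -> pd.DataFrame:
    """Per-method tau/MAE/RMSE ± sigma on a shared edge set.

    ``runs`` maps a method name to a DataFrame with columns ``ligand_i``,
    ``ligand_j``, ``ddg_calc`` and ``ddg_exp``.  All methods must cover the
    identical set of (pair, experimental value) rows, otherwise the
    statistics are not comparable and the call refuses.  Boolean columns
    flag the best method per metric (highest tau, lowest MAE/RMSE).
    """
    if not runs:
        raise InvalidInputError("no methods given")
    reference = None
    rows = []
    for method, df in runs.items():
        needed = {"ligand_i", "ligand_j", "ddg_calc", "ddg_exp"}
        if not needed.issubset(df.columns):
            raise InvalidInputError(
                f"method {method!r} is missing columns {needed - set(df.columns)}")
        edge_key = df.assign(
            _pair=[frozenset((i, j)) for i, j in
                   zip(df["ligand_i"], df["ligand_j"])])
        key = sorted((tuple(sorted(p)), round(float(e), 9))
                     for p, e in zip(edge_key["_pair"], df["ddg_exp"]))
        if reference is None:
            reference = key
        elif key != reference:
            raise InvalidInputError(
                f"method {method!r} covers a different edge set; "
                "statistics would not be comparable")
        stats = compute_benchmark(df["ddg_calc"].to_numpy(),
                                  df["ddg_exp"].to_numpy(),
                                  n_boot=n_boot, seed=seed)
        rows.append({
            "method": method, "n_pairs": stats.n_pairs,
            "kendall_tau": stats.kendall_tau, "tau_sigma": stats.tau_sigma,
            "mae": stats.mae, "mae_sigma": stats.mae_sigma,
            "rmse": stats.rmse, "rmse_sigma": stats.rmse_sigma,
        })
    table = pd.DataFrame(rows).set_index("method")
    table["best_tau"] = table["kendall_tau"] == table["kendall_tau"].max()
    table["best_mae"] = table["mae"] == table["mae"].min()
    table["best_rmse"] = table["rmse"] == table["rmse"].min()
    return table


def format_comparison_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of :func:`method_comparison_table` output."""
    lines = [f"{'method':<16s} {'tau':>14s} {'MAE':>14s} {'RMSE':>14s} "
             f"{'pairs':>6s}"]
    for method, row in table.iterrows():
        def cell(val, sig, best):
            text = f"{val:.2f} ± {sig:.2f}"
            return f"*{text}*" if best else f" {text} "
        lines.append(
            f"{method:<16s} "
            f"{cell(row['kendall_tau'], row['tau_sigma'], row['best_tau']):>14s} "
            f"{cell(row['mae'], row['mae_sigma'], row['best_mae']):>14s} "
            f"{cell(row['rmse'], row['rmse_sigma'], row['best_rmse']):>14s} "
            f"{int(row['n_pairs']):>6d}")
    return "\n".join(lines)


def scatter_plot(calc, exp, path, title: str = "calculated vs experimental"):
    """Optional calc-vs-exp scatter with ±1 and ±2 kcal/mol bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    calc, exp = _validated(calc, exp)
    lo = float(min(calc.min(), exp.min())) - 1.0
    hi = float(max(calc.max(), exp.max())) + 1.0
    fig, ax = plt.subplots(figsize=(5, 5))
    grid = np.array([lo, hi])
    ax.fill_between(grid, grid - 2, grid + 2, color="0.92")
    ax.fill_between(grid, grid - 1, grid + 1, color="0.82")
    ax.plot(grid, grid, "k-", lw=0.8)
    ax.plot(exp, calc, "o", ms=5)
    ax.set_xlim(lo, hi), ax.set_ylim(lo, hi)
    ax.set_xlabel("experimental (kcal/mol)")
    ax.set_ylabel("calculated (kcal/mol)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
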