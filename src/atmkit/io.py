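"""File formats: edge/node CSV, per-window sample CSV, XYZ, YAML configs.

All files are plain text, UTF-8, locale-independent (period decimal
separator), with energies in kcal/mol throughout.  Edge files carry an
explicit units comment that readers enforce.  Atom indices are 0-based in
every file, matching the API.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml

from ._version import __version__
from .alchemy import AlchemicalPotential, AlchemicalState
from .errors import ParseError
from .network import EdgeMeasurement, PerturbationNetwork
from .systems import EdgeSet, ToySystem
from .uwham import PerturbationSamples

__all__ = [
    "read_edges_csv", "write_edges_csv", "write_node_estimates_csv",
    "write_leg_samples", "read_leg_samples", "read_xyz", "write_xyz",
    "save_system", "load_system", "write_manifest",
]

UNITS_COMMENT = "# units: kcal/mol"
EDGE_COLUMNS = ["ligand_i", "ligand_j", "ddg_calc", "sigma_calc",
                "ddg_exp", "method"]


# --------------------------------------------------------------------------
# edge files
# --------------------------------------------------------------------------

def write_edges_csv(path, edges) -> None:
    """Write a ΔΔG edge table (convention: ddg = dG_j - dG_i).

    ``edges`` may be a :class:`PerturbationNetwork`, an :class:`EdgeSet`
    from the synthetic generator, or an iterable of
    :class:`EdgeMeasurement`.
    """
    if isinstance(edges, EdgeSet):
        measurements = [EdgeMeasurement(i, j, calc, sigma, exp)
                        for (i, j, calc, sigma, exp) in edges.edges]
    elif isinstance(edges, PerturbationNetwork):
        measurements = list(edges.edges)
    else:
        measurements = list(edges)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(UNITS_COMMENT + "\n")
        writer = csv.writer(fh)
        writer.writerow(EDGE_COLUMNS)
        for e in measurements:
            writer.writerow([
                e.i, e.j, repr(float(e.ddg)), repr(float(e.sigma)),
                "" if e.ddg_exp is None else repr(float(e.ddg_exp)),
                e.method or ""])


def read_edges_csv(path) -> PerturbationNetwork:
    """Read and validate an edge CSV into a :class:`PerturbationNetwork`.

    Enforces the kcal/mol units comment and the full header; parse errors
    name the offending file row and column.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path} is empty")
    body = []
    saw_units = False
    for lineno, raw in enumerate(lines, start=1):
        if raw.startswith("#"):
            if "kcal/mol" in raw:
                saw_units = True
            continue
        if raw.strip():
            body.append((lineno, raw))
    if not saw_units:
        raise ParseError(f"{path} is missing the '{UNITS_COMMENT}' comment")
    if not body:
        raise ParseError(f"{path} has no header row")
    header_line, header_raw = body[0]
    header = next(csv.reader([header_raw]))
    for col in ("ligand_i", "ligand_j", "ddg_calc", "sigma_calc"):
        if col not in header:
            raise ParseError("missing required column", row=header_line,
                             column=col)
    idx = {col: header.index(col) for col in header}
    edges = []
    for lineno, raw in body[1:]:
        row = next(csv.reader([raw]))
        if len(row) != len(header):
            raise ParseError(f"expected {len(header)} fields, got {len(row)}",
                             row=lineno)

        def cell(col, optional=False):
            val = row[idx[col]].strip() if col in idx else ""
            if not val and optional:
                return None
            return val

        def number(col, optional=False):
            val = cell(col, optional)
            if val is None:
                return None
            try:
                return float(val)
            except ValueError:
                raise ParseError(f"non-numeric value {val!r}", row=lineno,
                                 column=col) from None

        i, j = cell("ligand_i"), cell("ligand_j")
        if not i or not j:
            raise ParseError("empty ligand id", row=lineno,
                             column="ligand_i/ligand_j")
        sigma = number("sigma_calc")
        if not (sigma > 0):
            raise ParseError(f"sigma_calc must be > 0, got {sigma}",
                             row=lineno, column="sigma_calc")
        edges.append(EdgeMeasurement(
            i=i, j=j, ddg=number("ddg_calc"), sigma=sigma,
            ddg_exp=number("ddg_exp", optional=True),
            method=cell("method", optional=True)))
    return PerturbationNetwork(nodes={}, edges=edges)


def write_node_estimates_csv(path, estimates, net: PerturbationNetwork
                             ) -> None:
    """ligand, dG_calc, sigma, dG_exp, component -- one row per estimate."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write(UNITS_COMMENT + "\n")
        writer = csv.writer(fh)
        writer.writerow(["ligand", "dg_calc", "sigma", "dg_exp", "component"])
        for est in estimates:
            exp = net.nodes.get(est.ligand)
            writer.writerow([est.ligand, repr(est.dg), repr(est.sigma),
                             "" if exp is None else repr(float(exp)),
                             est.component])


# --------------------------------------------------------------------------
# per-window sample files
# --------------------------------------------------------------------------

def write_leg_samples(outdir, samples: PerturbationSamples,
                      schedule: list[AlchemicalState],
                      sample_interval: int = 1) -> None:
    """One CSV per lambda window: columns step, lam, u, u_sc, W."""
    from .alchemy import alchemical_bias, softcore
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if samples.u_series is None:
        raise ParseError("samples carry no raw u series to write")
    for k, state in enumerate(schedule):
        u = samples.u_series[k]
        u_sc = np.asarray(softcore(u, state.softcore))
        w = np.asarray(alchemical_bias(u_sc, state))
        fname = outdir / (f"leg{samples.leg}_rep{samples.replicate}"
                          f"_win{k:02d}.csv")
        with fname.open("w", encoding="utf-8", newline="") as fh:
            fh.write(UNITS_COMMENT + "\n")
            writer = csv.writer(fh)
            writer.writerow(["step", "lam", "u", "u_sc", "W"])
            for n, (uu, us, ww) in enumerate(zip(u, u_sc, w)):
                writer.writerow([(n + 1) * sample_interval,
                                 repr(state.lam), repr(float(uu)),
                                 repr(float(us)), repr(float(ww))])


def read_leg_samples(outdir, leg: int, replicate: int,
                     schedule: list[AlchemicalState], kT: float
                     ) -> PerturbationSamples:
    """Rebuild :class:`PerturbationSamples` from per-window CSVs.

    The cross-evaluated bias matrix is reconstructed from the raw u values
    and the schedule, since the ATM bias depends on the configuration only
    through u.
    """
    outdir = Path(outdir)
    u_rows = []
    for k in range(len(schedule)):
        fname = outdir / f"leg{leg}_rep{replicate}_win{k:02d}.csv"
        if not fname.exists():
            raise ParseError(f"missing window file {fname}")
        with fname.open("r", encoding="utf-8", newline="") as fh:
            rows = [r for r in csv.reader(
                line for line in fh if not line.startswith("#"))]
        header = rows[0]
        u_col = header.index("u")
        u_rows.append(np.array([float(r[u_col]) for r in rows[1:]]))
    n_min = min(len(u) for u in u_rows)
    u_series = np.stack([u[:n_min] for u in u_rows])
    # dummy system-free potential: bias matrix only needs the states
    from .alchemy import softcore as _softcore
    u_flat = u_series.reshape(-1)
    lam1 = np.array([s.lam1 for s in schedule])[:, None]
    lam2 = np.array([s.lam2 for s in schedule])[:, None]
    alpha = np.array([s.alpha for s in schedule])[:, None]
    u0 = np.array([s.u0 for s in schedule])[:, None]
    w0 = np.array([s.w0 for s in schedule])[:, None]
    u_sc = np.asarray(_softcore(u_flat, schedule[0].softcore))[None, :]
    bias = AlchemicalPotential._bias_broadcast(lam1, lam2, alpha, u0, w0,
                                               u_sc)
    counts = np.full(len(schedule), n_min, dtype=int)
    return PerturbationSamples(
        bias_matrix=bias / kT, sample_counts=counts,
        lambdas=np.array([s.lam for s in schedule]), leg=leg,
        replicate=replicate, kT=kT, u_series=u_series)


# --------------------------------------------------------------------------
# XYZ and system configs
# --------------------------------------------------------------------------

def write_xyz(path, coords: np.ndarray, comment: str = "",
              symbols=None) -> None:
    coords = np.asarray(coords, dtype=float)
    if symbols is None:
        symbols = ["C"] * coords.shape[0]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{coords.shape[0]}\n{comment}\n")
        for sym, (x, y, z) in zip(symbols, coords):
            fh.write(f"{sym} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path):
    """Returns (coords (N,3), symbols, comment)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    try:
        n = int(lines[0].strip())
    except (IndexError, ValueError):
        raise ParseError("XYZ file must start with an atom count", row=1)
    comment = lines[1] if len(lines) > 1 else ""
    coords, symbols = [], []
    for lineno, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError("XYZ row needs symbol and 3 coordinates",
                             row=lineno)
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    if len(coords) != n:
        raise ParseError(f"expected {n} atom rows, found {len(coords)}")
    return np.asarray(coords), symbols, comment


def save_system(path, system: ToySystem) -> None:
    """Serialize a toy system to a YAML config (documented, 0-based)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(system.to_dict(), fh, sort_keys=True)


def load_system(path) -> ToySystem:
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    try:
        return ToySystem.from_dict(data)
    except (KeyError, TypeError) as exc:
        raise ParseError(f"invalid system config {path}: {exc}") from exc


def write_manifest(path, payload: dict) -> None:
    """Replayable run manifest: full config, seeds and package version."""
    payload = dict(payload)
    payload.setdefault("atmkit_version", __version__)
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
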