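"""Maximum-likelihood absolute free energies from a ΔΔG edge network.

Each computed ligand-pair edge carries ddg(i -> j) = dG_j - dG_i plus a
standard error.  Per connected component, the node free energies minimize

    sum_edges (ddg_ij - (g_j - g_i))^2 / sigma_ij^2

under the gauge sum(g) = 0, solved through the pseudo-inverse of the
weighted graph Laplacian; per-node uncertainties are the square roots of
the pseudo-inverse diagonal.  Estimates are never mixed across components
-- a sparsely connected network simply yields several incomparable groups,
and anchoring to experiment happens per component by matching the mean of
the experimentally annotated nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .errors import InvalidInputError

__all__ = ["EdgeMeasurement", "PerturbationNetwork", "NodeEstimate",
           "check_connectivity", "mle_absolute_dg", "center_to_experiment"]


@dataclass(frozen=True)
class EdgeMeasurement:
    """One computed ligand-pair relative free energy, kcal/mol."""

    i: str
    j: str
    ddg: float
    sigma: float
    ddg_exp: float | None = None
    method: str | None = None

    def __post_init__(self):
        if self.i == self.j:
            raise InvalidInputError(f"self edge on ligand {self.i!r}")
        if not (self.sigma > 0):
            raise InvalidInputError(
                f"edge {self.i}-{self.j} needs sigma > 0, got {self.sigma}")


@dataclass
class PerturbationNetwork:
    """Ligand nodes (with optional experimental dG) plus ΔΔG edges."""

    nodes: dict[str, float | None]      # ligand id -> experimental dG or None
    edges: list[EdgeMeasurement] = field(default_factory=list)

    def __post_init__(self):
        for e in self.edges:
            for node in (e.i, e.j):
                self.nodes.setdefault(node, None)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.i, e.j)
        return g


@dataclass(frozen=True)
class NodeEstimate:
    """Maximum-likelihood absolute dG for one ligand (kcal/mol)."""

    ligand: str
    dg: float
    sigma: float
    component: int


def check_connectivity(net: PerturbationNetwork) -> list[list[str]]:
    """Connected components of the edge graph, largest first.

    Isolated ligands come back as singleton components; more than one
    component means absolute dG values cannot be compared network-wide.
    """
    comps = [sorted(c) for c in nx.connected_components(net.graph())]
    return sorted(comps, key=lambda c: (-len(c), c))


def mle_absolute_dg(net: PerturbationNetwork) -> list[NodeEstimate]:
    """Weighted least-squares node free energies, per connected component.

    Solves the normal equations L g = b with the weighted graph Laplacian
    L (weights 1/sigma^2) through its pseudo-inverse, which lands on the
    zero-mean gauge within each component.  Node sigmas are
    sqrt(diag(L^+)).  Singleton components carry no information and get no
    estimate.
    """
    estimates: list[NodeEstimate] = []
    components = check_connectivity(net)
    edges_by_node: dict[str, list[EdgeMeasurement]] = {}
    for e in net.edges:
        edges_by_node.setdefault(e.i, []).append(e)
        edges_by_node.setdefault(e.j, []).append(e)
    for comp_id, comp in enumerate(components):
        if len(comp) < 2:
            continue
        index = {node: m for m, node in enumerate(comp)}
        m = len(comp)
        lap = np.zeros((m, m))
        b = np.zeros(m)
        seen = set()
        for node in comp:
            for e in edges_by_node.get(node, []):
                if id(e) in seen:
                    continue
                seen.add(id(e))
                wi, wj = index[e.i], index[e.j]
                w = 1.0 / (e.sigma * e.sigma)
                lap[wi, wi] += w
                lap[wj, wj] += w
                lap[wi, wj] -= w
                lap[wj, wi] -= w
                b[wj] += w * e.ddg
                b[wi] -= w * e.ddg
        lap_pinv = np.linalg.pinv(lap, hermitian=True)
        g = lap_pinv @ b
        g = g - g.mean()  # zero-mean gauge (pinv already lands here)
        sig = np.sqrt(np.maximum(np.diag(lap_pinv), 0.0))
        for node in comp:
            k = index[node]
            estimates.append(NodeEstimate(ligand=node, dg=float(g[k]),
                                          sigma=float(sig[k]),
                                          component=comp_id))
    return estimates


def center_to_experiment(estimates: list[NodeEstimate],
                         net: PerturbationNetwork) -> list[NodeEstimate]:
    """Shift each component so its mean matches the experimental mean.

    The shift is computed over the nodes of the component that carry an
    experimental dG; components with no experimental anchor are left in the
    zero-mean gauge with a warning.  Sigmas are unchanged, and the
    operation is idempotent.
    """
    out: list[NodeEstimate] = []
    by_comp: dict[int, list[NodeEstimate]] = {}
    for est in estimates:
        by_comp.setdefault(est.component, []).append(est)
    for comp_id, comp_estimates in sorted(by_comp.items()):
        anchored = [(est.dg, net.nodes.get(est.ligand))
                    for est in comp_estimates
                    if net.nodes.get(est.ligand) is not None]
        if not anchored:
            warnings.warn(
                f"component {comp_id} has no experimental anchor; "
                "leaving it in the zero-mean gauge", stacklevel=2)
            out.extend(comp_estimates)
            continue
        calc_mean = np.mean([a[0] for a in anchored])
        exp_mean = np.mean([a[1] for a in anchored])
        shift = float(exp_mean - calc_mean)
        out.extend(replace(est, dg=est.dg + shift) for est in comp_estimates)
    return out
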