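"""Absolute dG per ligand from a ΔΔG perturbation network.

Generates a synthetic 8-ligand edge network with Gaussian edge noise,
reconstructs per-ligand free energies by maximum likelihood over the
graph, and compares them with the generating truth.
"""

import numpy as np

import atmkit as ak

edge_set = ak.make_edge_network(n_ligands=8, edge_fraction=0.7,
                                noise_sigma=0.3, seed=5)
net = ak.PerturbationNetwork(nodes={}, edges=[
    ak.EdgeMeasurement(i, j, calc, sigma)
    for (i, j, calc, sigma, _exp) in edge_set.edges])

components = ak.check_connectivity(net)
print(f"{len(net.edges)} edges over {len(edge_set.nodes)} ligands, "
      f"{len(components)} connected component(s)")

estimates = ak.mle_absolute_dg(net)
true_centered = {k: v - np.mean(list(edge_set.true_dgs.values()))
                 for k, v in edge_set.true_dgs.items()}

print(f"{'ligand':>8s} {'dG_fit':>8s} {'sigma':>7s} {'dG_true':>8s}")
sq = []
for est in estimates:
    truth = true_centered[est.ligand]
    sq.append((est.dg - truth) ** 2)
    print(f"{est.ligand:>8s} {est.dg:+8.3f} {est.sigma:7.3f} {truth:+8.3f}")
print(f"\nnode RMSE vs truth: {np.sqrt(np.mean(sq)):.3f} kcal/mol "
      "(edge noise was 0.3 kcal/mol; averaging over edges shrinks it)")
print("Values are in the zero-mean gauge: only differences are physical")
print("until the network is anchored to experimental dG values.")
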