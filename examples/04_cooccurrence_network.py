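"""Build a co-occurrence network and analyse its topology and robustness.

Simulates communities whose OTUs respond to a shared environmental gradient
(so real correlations exist), builds the Spearman/FDR network, and reports
global topology, a matched Erdős-Rényi baseline, Zi-Pi keystone roles and
the natural-connectivity robustness curve.
"""

import numpy as np

from ecoassembly import (
    build_network,
    detect_modules,
    filter_for_network,
    graph_topology,
    natural_connectivity,
    random_ensemble,
    robustness_curve,
    simulate_metacommunity,
    simulate_niche_local,
    simulate_tree_with_traits,
    zipi_classify,
)

pool = simulate_metacommunity(n_otus=200, lognormal_sd=1.5, seed=41)
tree, traits = simulate_tree_with_traits(n_otus=200, seed=42)
sd = float(traits.std())
env = np.linspace(-2 * sd, 2 * sd, 24)  # smooth gradient across samples
table, _ = simulate_niche_local(pool, traits, env, sigma_sel=1.0 * sd,
                                n_individuals=2000, seed=43)

filtered = filter_for_network(table, min_occupancy=0.5, top_n=150)
g = build_network(filtered, rho_min=0.6, q_max=0.01)
topo = graph_topology(g, seed=44)

print(f"network: {topo.n_nodes} nodes, {topo.n_edges} edges "
      f"({topo.positive_edge_fraction:.0%} positive)")
print(f"average degree {topo.average_degree:.2f}, density {topo.density:.3f}, "
      f"clustering {topo.average_clustering:.3f}")
print(f"modularity Q = {topo.modularity:.3f} over {topo.n_modules} modules "
      f"({'modular' if topo.modularity > 0.4 else 'weakly modular'})")

baseline = random_ensemble(topo.n_nodes, topo.n_edges, reps=200, seed=45)
print(f"matched random graphs: clustering {baseline.clustering_mean:.3f} "
      f"(±{baseline.clustering_sd:.3f}), modularity {baseline.modularity_mean:.3f}")

modules, _ = detect_modules(g, seed=44)
roles = zipi_classify(g, modules)
keystones = roles[roles["keystone"]]
print(f"keystone taxa (hubs + connectors): {len(keystones)}")

curve = robustness_curve(g, strategy="degree_desc")
print(f"natural connectivity: {natural_connectivity(g):.3f} intact, "
      f"{curve.nc_mean[len(curve.nc_mean) // 2]:.3f} after removing "
      f"{curve.removal_fraction[len(curve.nc_mean) // 2]:.0%} of hubs")
print()
print(
    "Empirical clustering far above the random baseline marks a non-random,\n"
    "gradient-structured network; the robustness curve shows how fast\n"
    "structural redundancy is lost when the most connected taxa are removed."
)
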