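"""Environmental heterogeneity and the community-environment link.

Generates seasonal environments whose between-site spread peaks in
winter, computes the heterogeneity index H (mean pairwise Euclidean
distance between sites, variables z-scored across all samples), and
runs a Mantel test between community and environmental distance for a
strongly filtered metacommunity.
"""

from ecoassembly import (
    SimulationConfig,
    bray_curtis_matrix,
    euclidean_matrix,
    generate_environments,
    heterogeneity_index,
    mantel_test,
    simulate_dataset,
)

env = generate_environments(13, seed=5)
het = heterogeneity_index(env)
print("environmental heterogeneity per season (z-scored variables):")
print(het.round(3).to_string())
print("winter sites spread widely along the temperature axis, summer "
      "sites barely differ — H tracks that spread.\n")

cfg = SimulationConfig(n_taxa=150, n_sites=15, community_size=1000,
                       niche_width=2.0, seasons={"one": (16.0, 8.0)}, seed=6)
ds = simulate_dataset(cfg)
bc = bray_curtis_matrix(ds.otu_table)
envd = euclidean_matrix(ds.env, standardize=True).loc[bc.index, bc.index]
r, p = mantel_test(bc, envd, n_perm=999, seed=7)
print(f"Mantel test, Bray-Curtis vs environmental distance: r = {r:.2f}, "
      f"p = {p:.3f} (999 permutations)")
print("strong filtering across divergent sites couples community "
      "turnover to the environment; under pure drift r collapses to ~0")
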