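"""Gene-set over-representation of up-regulated DEGs, with radar export.

Builds a small gene-set collection over the simulated gene namespace, plants
one set enriched among the up-regulated genes of each comparison, scores
every set with the one-sided Fisher/hypergeometric tail + BH-FDR, and clips
-log10(q) into a fixed band for radar plotting.
"""

import numpy as np

from ihtseq import (
    ComparisonConfig, GeneSetCollection, SimConfig, fisher_enrichment,
    radar_values, run_comparison, simulate_counts,
)

counts, design, truth = simulate_counts(SimConfig(n_genes=1500, seed=3))

tables = {}
for trt in ("KSO", "Fib"):
    table, _ = run_comparison(counts, design, trt, "control", ComparisonConfig(seed=1))
    tables[trt] = table

universe = tables["Fib"]["gene_id"].tolist()
rng = np.random.default_rng(0)
sets = {}
for trt, table in tables.items():
    up = table.loc[table.direction == "up", "gene_id"].tolist()
    planted = up[:15] + list(rng.choice(universe, 20, replace=False))
    sets[f"RESPONSE_{trt}"] = (f"genes responding to {trt}", sorted(set(planted)))
sets["RANDOM"] = ("background set", list(rng.choice(universe, 40, replace=False)))
collection = GeneSetCollection(sets)

enrichments = {}
for trt, table in tables.items():
    up = table.loc[table.direction == "up", "gene_id"].tolist()
    result = fisher_enrichment(up, universe, collection)
    enrichments[trt] = result
    for _, row in result.iterrows():
        print(f"{trt:>4}  {row.set_id:<14} k={row.k:>3}/{row.K:<3} "
              f"q={row.q_fdr:.3g} {'*' if row.significant else ''}")

spec = radar_values(enrichments, list(collection.names()), cap_max=6.0)
print("\nradar matrix (capped -log10 q; rows = comparisons):")
print(spec.values.round(2).to_string())
print("values at 6.0 hit the display cap; 0 means no enrichment signal")
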