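"""Normalize simulated counts and check that samples cluster by tissue.

Runs the CPM filter, TMM factors and log2 CPM, then projects samples with
classical MDS on leading-fold-change distances — the standard QC view in
which tissues should form distinct clusters.
"""

import crossmode as cm
from sklearn.metrics import silhouette_score

design = cm.make_design()
config = cm.SimulationConfig(n_genes=1000, seed=2)
matrix = cm.simulate_counts(design, cm.assign_gene_truth(config), config)

filtered = cm.filter_low_expression(matrix, cpm_threshold=0.5, min_samples=3)
print(f"expression filter: {matrix.shape[0]} -> {filtered.shape[0]} genes "
      f"(CPM >= 0.5 in >= 3 samples)")

factors = cm.tmm_factors(filtered)
print(f"TMM factors: {factors.min():.3f}-{factors.max():.3f} "
      f"(geometric mean 1 by construction)")

logmat = cm.log_cpm(filtered, factors)
coords = cm.mds_coordinates(logmat, k=2)
labels = design.set_index("sample_id").loc[coords.index, "tissue"]
score = silhouette_score(coords.to_numpy(), labels)
print(f"MDS silhouette vs tissue labels: {score:.2f} "
      f"(> 0 means samples group by tissue, as in real data)")
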