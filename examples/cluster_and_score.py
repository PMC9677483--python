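"""Cluster a dataset from a distance matrix and score it against truth.

Distance matrix -> KNN graph -> Leiden with automatic resolution tuning
(until the ground-truth cluster count is found) -> PSI / ARI / AMI.
"""

from proxeval import (SynthConfig, build_knn_graph, cluster_replicates,
                      compute_distance_matrix, generate_discrete,
                      normalize_log, score_partition)

ds = generate_discrete(SynthConfig(n_cells=500, n_genes=600, seed=9))
norm = normalize_log(ds)
dist = compute_distance_matrix(norm, "pearson")
graph = build_knn_graph(dist, k=10)

n_types = len(set(ds.labels))
parts = cluster_replicates(graph, target_clusters=n_types, n_seeds=5,
                           base_seed=0)
for i, p in enumerate(parts):
    psi, ari, ami = score_partition(ds.labels, p.labels)
    print(f"seed {i}: {p.n_clusters} clusters at resolution "
          f"{p.resolution:.3g} (attempts {p.attempts}, converged "
          f"{p.converged})  PSI={psi:.3f}  ARI={ari:.3f}  AMI={ami:.3f}")

print("\nPSI = 1 means every planted population was recovered exactly"
      "\n(up to label names); the resolution printed is the value the tuner"
      "\nneeded to produce exactly the ground-truth cluster count.")
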