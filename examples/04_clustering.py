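"""Sample-profile clustering: do conditions separate?

Samples are compared by the Spearman correlation of their expression
profiles and clustered with average linkage on distance 1 - rho.  Cutting
the tree into two clusters and scoring purity against the group labels
shows whether the normal/cancer split is recovered.
"""

from hkatlas import SimConfig, cluster_samples, simulate_study

study = simulate_study(SimConfig(n_genes=10_000, seed=42), n_intergenic=100)
matrix = study["matrix"]

tree, partition, purity = cluster_samples(matrix)
print(f"two-group purity: {purity}")
print("cluster membership:")
for cluster_id in sorted(set(partition.values())):
    members = [s for s, c in partition.items() if c == cluster_id]
    print(f"  cluster {cluster_id}: {' '.join(members)}")
print("\nNewick tree:")
print(tree.to_newick())
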