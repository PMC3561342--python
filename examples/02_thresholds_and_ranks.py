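"""Tri-level expression thresholds and rank-based variation statuses.

Expressed genes of each sample are split into low / moderate / high classes
by 1-D weighted k-medians on log2(x + 1); the unified (low, high) thresholds
are the medians over the normal samples.  Every expressed cell is then
mapped to a rank 1/2/3, and each gene's coefficient of variation over its
normal-group ranks classifies it as constant, moderately variable or
variable.
"""

from hkatlas import (SimConfig, assign_ranks, build_catalog, cv_table,
                     cv_thresholds, per_sample_backgrounds, simulate_study,
                     status_table, trilevel_table, unified_background)

study = simulate_study(SimConfig(n_genes=10_000, seed=42), n_intergenic=5_000)
matrix, intergenic = study["matrix"], study["intergenic"]
background = unified_background(per_sample_backgrounds(matrix, intergenic).values())

table, (low, high) = trilevel_table(matrix, background, seed=0, max_restarts=10)
print("per-sample tri-level rows (first 4):")
print(table.head(4).to_string(float_format=lambda v: f"{v:.3f}"))
print(f"\nunified thresholds: low = {low:.3f} RPKM, high = {high:.3f} RPKM")

catalog = build_catalog(matrix, background)
ranks = assign_ranks(matrix.values, low, high, background)
normal_cols = matrix.group_columns("normal")
cvs = cv_table(ranks.loc[sorted(catalog.normal_hk), normal_cols])
q1, q3 = cv_thresholds(cvs.to_numpy())
statuses = status_table(cvs, q1, q3)
print(f"\nnormal-group HK CV quartiles: q1 = {q1:.3f}, q3 = {q3:.3f}")
print("status distribution:")
print(statuses.value_counts().to_string())
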