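# Data dictionary

Column definitions for every table written by `hkatlas run-all` (and the
corresponding stage subcommands). All expression values are RPKM; all
rounding is half-up.

## background_thresholds.tsv
| column | meaning |
|---|---|
| sample_id | sample identifier |
| threshold | per-sample background cutoff (argmin \|FPR − FNR\|) |

The CLI `background` subcommand appends a `unified_median` row.

## hk_catalog.tsv
| column | meaning |
|---|---|
| gene_id | gene identifier (index) |
| hk_class | one of `shared`, `normal_unique`, `cancer_associated`, `non_HK` |

## hk_accounting.tsv
| column | meaning |
|---|---|
| (index) | class or derived set (`normal_HK`, `cancer_HK`) |
| count | number of genes |
| percent_of_loci | integer percent of `total_loci`, half-up |

## trilevel_thresholds.tsv
| column | meaning |
|---|---|
| (index) | sample id |
| low_count | genes in the low cluster (LEG) |
| low_threshold | midpoint of (max LEG, min MEG), original scale |
| moderate_count | genes in the moderate cluster (MEG) |
| high_count | genes in the high cluster (HEG) |
| high_threshold | midpoint of (max MEG, min HEG), original scale |
| total | expressed genes in the sample (above background) |

## cv_normal.tsv / cv_cancer.tsv
| column | meaning |
|---|---|
| (index) | gene id (HK genes of the group, fully expressed) |
| cv_normal / cv_cancer | coefficient of variation of tri-level ranks (population sd / mean) |
| status_normal / status_cancer | `constant` (CV ≤ q1), `moderate_variable` (q1 < CV ≤ q3), `variable` (CV > q3) |

## cv_transitions.tsv
3 × 3 counts over shared HK genes; rows = status in normal, columns =
status in cancer; row sums = per-status totals in normal.

## mdad_<class>.tsv
| column | meaning |
|---|---|
| (index) | gene id |
| max_n, min_n | max and positive min over normal samples (0 when absent) |
| max_c, min_c | same for cancer samples |
| MD | log2 span-width difference, normal − cancer; NaN when any extreme is 0 |
| AD | log2 mid-level difference, normal − cancer; NaN when any extreme is 0 |
| maxR | max_n / max_c (0 = off in normal, inf = off in cancer) |
| minR | min_n / min_c, same conventions |
| only_on_in_cancer / only_on_in_normal | one-sided expression flags |

## mdad_<class>_tests.tsv
| column | meaning |
|---|---|
| type | `<statistic>_<subset>`, e.g. `AD_all`, `MD_constant` |
| gene_count | genes entering the test (defined MD/AD only) |
| reject | 1 if the zero-median null is rejected at α = 0.05 |
| p_value | two-sided signed-rank p (exact for n ≤ 20) |
| z | signed normal deviate; sign of (W⁺ − n(n+1)/4) |

## ratio_accumulation_<class>.tsv
| column | meaning |
|---|---|
| type | `all` or a variation status |
| gene_count | genes in the subset |
| minR_le_cutoff_pct | percent with minR ≤ 1, two decimals |
| maxR_le_cutoff_pct | percent with maxR ≤ 1, two decimals |

## profile_tree.nwk
Newick serialisation of the average-linkage tree over samples (distance
1 − Spearman ρ).

## cluster_partition.tsv
| column | meaning |
|---|---|
| sample_id | sample identifier |
| cluster | 2-way cluster assignment (integer) |

## gene_structure.tsv
| column | meaning |
|---|---|
| (index) | gene id |
| gene_size_bp | representative-transcript span (first exon start to last exon end) |
| cds_length_bp | CDS length of the representative transcript |
| n_exons | exon count |
| n_minimal_introns | introns ≤ 125 bp (configurable) |
| n_large_introns | introns ≥ 50,000 bp (configurable) |
| gc_content | sequence GC fraction |

## structure_bias.tsv
| column | meaning |
|---|---|
| hk_class, feature | (index) class and structural feature |
| n_class | genes in the class |
| class_median | median feature value in the class |
| background_median | median over the remaining genes |
| p_value | two-sided Mann-Whitney class vs complement |
| direction | −1 class below background, +1 above (only when p < α), else 0 |

## truth.tsv (simulated runs only)
| column | meaning |
|---|---|
| (index) | gene id |
| hk_class | planted class (`tissue_specific` = HK in neither group) |
| log2fc | planted cancer fold change (0 when not up-regulated) |
| level_mode_normal / level_mode_cancer | planted expression mode (1/2/3) |
| variation_normal / variation_cancer | planted variation status |

## run_manifest.json
Machine-readable record of the run: package version, seed, the full
pipeline configuration, the unified background threshold, unified low/high
thresholds, CV quartiles and two-group clustering purity.
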