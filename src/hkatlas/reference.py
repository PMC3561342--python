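"""Published reference values from the 12-normal-tissue / 9-cancer-cell-line
human RNA-Seq survey that this pipeline re-implements.

These constants are inputs for worked examples and consistency checks: the
per-tissue tri-level threshold table, the headline housekeeping-gene counts,
and the accumulated maxR/minR percentages for shared and cancer-associated
HK genes.  They are printed values, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

# Per-normal-tissue tri-level rows: gene count below the low threshold, the
# low threshold (RPKM), moderate gene count, high gene count, the high
# threshold (RPKM) and the expressed-gene total.
NORMAL_TISSUE_TRILEVEL = pd.DataFrame(
    [
        ("Adipose",         3101, 1.20,  8505, 1313, 19.99, 12919),
        ("Brain",           2949, 1.22,  8903, 1553, 13.14, 13405),
        ("Breast",          3311, 1.18,  8985, 1289, 17.66, 13585),
        ("Cerebral Cortex", 3385, 0.66,  9094, 1522,  9.47, 14001),
        ("Colon",           3402, 1.18,  8570, 1300, 18.00, 13272),
        ("Heart",           2855, 0.88,  7950, 1386,  9.99, 12191),
        ("Kidney",          2868, 0.80,  8991, 1710,  8.58, 13695),
        ("Liver",           2895, 0.85,  7679, 1509, 12.30, 12083),
        ("Lung",            3399, 0.71,  9111, 1482,  9.99, 13992),
        ("Lymph Node",      3229, 1.19,  8994, 1656, 14.43, 13879),
        ("Muscle",          4769, 1.18,  5872, 1072, 18.69, 11713),
        ("Testis",          2538, 0.93, 10425, 3004, 11.75, 15967),
    ],
    columns=["sample", "low_count", "low_threshold", "moderate_count",
             "high_count", "high_threshold", "total"],
).set_index("sample")

# Headline housekeeping-gene accounting over 18,874 protein-coding loci.
TOTAL_LOCI = 18_874
NORMAL_HK_COUNT = 8_831
CANCER_HK_COUNT = 7_084
SHARED_HK_COUNT = 6_237

# Reported unified background threshold (median of per-sample values that
# ranged over 0.13-0.41 RPKM).
BACKGROUND_RPKM = 0.25
BACKGROUND_RANGE_RPKM = (0.13, 0.41)

# Reported unified tri-level thresholds (medians of the normal-tissue rows).
UNIFIED_LOW_RPKM = 1.06
UNIFIED_HIGH_RPKM = 12.72

# Reported CV quartiles of the normal-group HK genes.
CV_Q1 = 0.14
CV_Q3 = 0.26

# Accumulated ratio tables: percent of genes with minR <= 1 / maxR <= 1,
# per variation-status subtype, for shared and cancer-associated HK genes.
SHARED_RATIO_TABLE = pd.DataFrame(
    [
        ("all",      6237, 73.47, 67.79),
        ("constant", 1518, 78.24, 70.17),
        ("moderate", 3812, 65.10, 62.30),
        ("variable",  907, 80.16, 73.53),
    ],
    columns=["type", "gene_count", "minR_le_1_pct", "maxR_le_1_pct"],
).set_index("type")

CANCER_ASSOCIATED_RATIO_TABLE = pd.DataFrame(
    [
        ("all",      847, 87.25, 78.51),
        ("constant", 105, 75.24, 74.29),
        ("moderate", 361, 93.63, 78.39),
        ("variable", 381, 84.51, 79.79),
    ],
    columns=["type", "gene_count", "minR_le_1_pct", "maxR_le_1_pct"],
).set_index("type")
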