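"""Gene-structure features and per-HK-class bias summaries.

Six architectural features are extracted per gene from its representative
transcript (the one with the longest CDS): gene span, CDS length, exon
count, counts of minimal and large introns, and sequence GC fraction.
Each HK class is then compared with the genome background (the remaining
genes) feature by feature with a two-sided rank-sum test, flagging the
direction of any shift - e.g. AT-richness or avoidance of large genes in
the cancer-associated class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import HKCatalog
from .core import GeneModel, InvalidInputError

# Intron length cutoffs (bp).  Configurable; defaults follow common usage in
# the gene-architecture literature.
MINIMAL_INTRON_MAX_BP = 125
LARGE_INTRON_MIN_BP = 50_000

FEATURES = ("gene_size_bp", "cds_length_bp", "n_exons",
            "n_minimal_introns", "n_large_introns", "gc_content")


@dataclass
class GeneStructure:
    gene_id: str
    gene_size_bp: int
    cds_length_bp: int
    n_exons: int
    n_minimal_introns: int
    n_large_introns: int
    gc_content: float


def gene_structure(model: GeneModel,
                   minimal_intron_max_bp: int = MINIMAL_INTRON_MAX_BP,
                   large_intron_min_bp: int = LARGE_INTRON_MIN_BP) -> GeneStructure:
    """Structural features from the representative (longest-CDS) transcript."""
    tx = model.representative_transcript()
    exons = sorted(model.exons[tx])
    if not exons:
        raise InvalidInputError(f"{model.gene_id}: zero exons")
    introns = [exons[i + 1][0] - exons[i][1] for i in range(len(exons) - 1)]
    return GeneStructure(
        gene_id=model.gene_id,
        gene_size_bp=exons[-1][1] - exons[0][0],
        cds_length_bp=model.cds_length_bp.get(tx, sum(e - s for s, e in exons)),
        n_exons=len(exons),
        n_minimal_introns=sum(1 for i in introns if i <= minimal_intron_max_bp),
        n_large_introns=sum(1 for i in introns if i >= large_intron_min_bp),
        gc_content=model.sequence_gc,
    )


def gc_fraction(sequence: str) -> float:
    """GC fraction of a nucleotide string (case-insensitive)."""
    seq = sequence.upper()
    if not seq:
        raise InvalidInputError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def structure_table(models, **cutoffs) -> pd.DataFrame:
    rows = [vars(gene_structure(m, **cutoffs)) for m in models]
    return pd.DataFrame(rows).set_index("gene_id")


def class_bias(structures: pd.DataFrame, catalog: HKCatalog,
               alpha: float = 0.05) -> pd.DataFrame:
    """Per-class medians and rank-sum comparisons against the genome
    background (the class complement) for every structural feature.

    Output rows are (hk_class, feature) with the class median, background
    median, two-sided Mann-Whitney p-value and a direction flag
    (-1 class-below-background, +1 above, 0 not significant at *alpha*).
    """
    missing = set(catalog.base_class) - set(structures.index)
    if missing:
        raise InvalidInputError(f"structures missing for genes: {sorted(missing)[:5]}")
    class_sets = {
        "shared": catalog.shared,
        "normal_unique": catalog.normal_unique,
        "cancer_associated": catalog.cancer_associated,
        "normal_HK": catalog.normal_hk,
        "cancer_HK": catalog.cancer_hk,
    }
    rows = []
    all_genes = [g for g in structures.index if g in catalog.base_class]
    for cname, genes in class_sets.items():
        members = [g for g in all_genes if g in genes]
        rest = [g for g in all_genes if g not in genes]
        if not members:
            continue  # empty class: skipped
        if not rest:
            # class covers the whole genome: zero shift by definition
            for feat in FEATURES:
                med = float(np.median(structures.loc[members, feat]))
                rows.append({"hk_class": cname, "feature": feat, "n_class": len(members),
                             "class_median": med, "background_median": med,
                             "p_value": 1.0, "direction": 0})
            continue
        for feat in FEATURES:
            a = structures.loc[members, feat].to_numpy(dtype=float)
            b = structures.loc[rest, feat].to_numpy(dtype=float)
            stat = sps.mannwhitneyu(a, b, alternative="two-sided")
            direction = 0
            if stat.pvalue < alpha:
                direction = 1 if np.median(a) > np.median(b) else -1
            rows.append({
                "hk_class": cname, "feature": feat, "n_class": len(members),
                "class_median": float(np.median(a)),
                "background_median": float(np.median(b)),
                "p_value": float(stat.pvalue), "direction": direction,
            })
    return pd.DataFrame(rows).set_index(["hk_class", "feature"])
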