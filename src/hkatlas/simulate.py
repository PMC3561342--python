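"""Synthetic two-group RNA-Seq study generator with planted ground truth.

Emulates the design of a 12-normal-tissue / 9-cancer-cell-line bulk RNA-Seq
comparison so that every downstream stage (background thresholding, HK
classification, tri-level thresholds, variation classes, MDAD statistics,
profile clustering, structure bias) can be tested against known truth:

* genes are planted into HK classes (shared / normal-unique /
  cancer-associated / tissue-specific) via per-sample on/off masks;
* expressed values come from a tri-modal log-normal mixture (low / moderate /
  high modes with a heavy right tail), with a per-status rank template that
  plants each gene's expression-variation status (constant / moderate
  variable / variable against the 0.14 / 0.26 CV cutoffs);
* a configurable fraction of shared and cancer-associated genes is
  systematically up-regulated in the cancer group by a log2 fold change;
* silent gene-samples draw from the intergenic density (mostly exact zeros,
  as genes without reads have RPKM 0), and intergenic regions provide the
  negative set for background thresholding;
* cancer-associated genes get an AT-rich (lower GC) annotation shift.

Randomness: every stage derives its own substream from the single config
seed (``default_rng([stage_index, seed])``), so each generator function is
bit-reproducible in isolation and jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CANCER, NORMAL, ExpressionMatrix, GeneModel, InvalidInputError, SampleMeta
from .variation import CONSTANT, MODERATE_VARIABLE, VARIABLE, DEFAULT_Q1, DEFAULT_Q3

CLASSES = ("shared", "normal_unique", "cancer_associated", "tissue_specific")

_ANNOT_STREAM, _EXPR_STREAM, _INTERGENIC_STREAM = 0, 1, 2


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults emulate a two-group bulk RNA-Seq design: expression modes near
    0.5 / 6 / 60 RPKM separated widely enough that the tri-level boundaries
    fall in the inter-mode gaps, an intergenic density far below the low
    mode, and 12 + 9 samples.
    """

    n_genes: int = 10_000
    n_normal_samples: int = 12
    n_cancer_samples: int = 9
    class_fractions: dict = field(default_factory=lambda: {
        "shared": 0.50, "normal_unique": 0.20,
        "cancer_associated": 0.10, "tissue_specific": 0.20,
    })
    # (natural-log mean, natural-log sd) per mode: low, moderate, high
    level_mixture: tuple = (
        (math.log(0.5), 0.25),
        (math.log(6.0), 0.35),
        (math.log(60.0), 0.30),
    )
    level_weights: tuple = (0.25, 0.62, 0.13)
    dropout_rate: float = 0.4
    cancer_upregulation_log2fc: float = 1.0
    upregulated_fraction: float = 0.7
    variation_sd: float = 0.12  # per-cell multiplicative noise, ln scale
    variation_fractions: dict = field(default_factory=lambda: {
        CONSTANT: 0.40, MODERATE_VARIABLE: 0.35, VARIABLE: 0.25,
    })
    intergenic_density: tuple = (math.log(0.03), 0.7)
    silent_zero_fraction: float = 0.9
    at_rich_shift: float = 0.05
    cancer_size_factor: float = 1.0  # <1 shrinks cancer_associated introns (large-gene depletion)
    force_zero: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 4:
            raise InvalidInputError("n_genes must be >= 4 to host all classes")
        if self.n_normal_samples < 1 or self.n_cancer_samples < 1:
            raise InvalidInputError("both groups need at least one sample")
        for fractions, name in ((self.class_fractions, "class_fractions"),
                                (self.variation_fractions, "variation_fractions")):
            if abs(sum(fractions.values()) - 1.0) > 1e-9:
                raise InvalidInputError(f"{name} must sum to 1")
            if any(v < 0 for v in fractions.values()):
                raise InvalidInputError(f"{name} must be non-negative")
        if set(self.class_fractions) != set(CLASSES):
            raise InvalidInputError(f"class_fractions keys must be {CLASSES}")
        for _, sd in list(self.level_mixture) + [self.intergenic_density]:
            if sd < 0:
                raise InvalidInputError("log-sd parameters must be >= 0")
        if self.variation_sd < 0:
            raise InvalidInputError("variation_sd must be >= 0")
        if not 0 <= self.silent_zero_fraction <= 1:
            raise InvalidInputError("silent_zero_fraction must be in [0, 1]")
        if not 0 <= self.dropout_rate <= 1:
            raise InvalidInputError("dropout_rate must be in [0, 1]")
        if self.cancer_upregulation_log2fc < 0:
            raise InvalidInputError("cancer_upregulation_log2fc must be >= 0")
        if not 0 <= self.upregulated_fraction <= 1:
            raise InvalidInputError("upregulated_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth: per-gene table + the silent (off) mask."""

    table: pd.DataFrame          # indexed by gene_id
    silent_mask: pd.DataFrame    # bool, genes x samples; True = planted off


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _class_assignment(config: SimConfig) -> list[str]:
    """Deterministic blockwise class assignment honouring the fractions."""
    counts = {c: int(math.floor(config.class_fractions[c] * config.n_genes))
              for c in CLASSES}
    rem = config.n_genes - sum(counts.values())
    for c in CLASSES:
        if rem == 0:
            break
        if config.class_fractions[c] > 0:
            counts[c] += 1
            rem -= 1
    out: list[str] = []
    for c in CLASSES:
        out.extend([c] * counts[c])
    return out[: config.n_genes]


# -------------------------------------------------------------- annotation


def simulate_annotation(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Synthetic single-transcript gene models along one chromosome.

    Exon counts are 1 + Poisson(7); exon lengths ~ lognormal(ln 150, 0.6);
    intron lengths ~ lognormal(ln 1500, 1.6), whose heavy tail yields both
    minimal (<= 125 bp) and large (>= 50 kb) introns.  GC ~ N(0.46, 0.07),
    lowered by ``at_rich_shift`` for cancer-associated genes.  Returns the
    models plus a per-gene truth frame (class, GC).
    """
    rng = np.random.default_rng([_ANNOT_STREAM, config.seed])
    ids = _gene_ids(config.n_genes)
    classes = _class_assignment(config)
    models = []
    rows = []
    cursor = 10_000
    for gid, cls in zip(ids, classes):
        n_exons = 1 + int(rng.poisson(7))
        exon_lens = np.maximum(30, rng.lognormal(math.log(150), 0.6, n_exons).astype(int))
        size_factor = config.cancer_size_factor if cls == "cancer_associated" else 1.0
        intron_lens = (np.maximum(40, (size_factor *
                                       rng.lognormal(math.log(1500), 1.6, max(0, n_exons - 1)))
                                  .astype(int)) if n_exons > 1 else np.array([], dtype=int))
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(intron_lens):
                pos += int(intron_lens[i])
        cursor = pos + 10_000
        gc = float(rng.normal(0.46, 0.07))
        if cls == "cancer_associated":
            gc -= config.at_rich_shift
        gc = float(np.clip(gc, 0.2, 0.8))
        tx = f"{gid}.t1"
        models.append(GeneModel(gene_id=gid, chrom="chrS", strand="+" if rng.random() < 0.5 else "-",
                                exons={tx: exons},
                                cds_length_bp={tx: int(exon_lens.sum())},
                                sequence_gc=gc))
        rows.append({"gene_id": gid, "hk_class": cls, "gc": gc})
    return models, pd.DataFrame(rows).set_index("gene_id")


# -------------------------------------------------------------- expression


def _rank_cv(ranks: np.ndarray) -> float:
    mu = ranks.mean()
    return float(np.sqrt(np.mean((ranks - mu) ** 2)) / mu)


def _rank_template(status: str, base_rank: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rank vector of length *n* whose CV lands in the band of *status*
    (against the default 0.14 / 0.26 cutoffs).  Deviant positions are
    shuffled; tiny groups fall back to the closest achievable pattern."""
    if n <= 1 or status == CONSTANT:
        return np.full(n, base_rank, dtype=float)
    toward = 2 if base_rank != 2 else (3 if rng.random() < 0.5 else 1)
    if status == MODERATE_VARIABLE:
        best = None
        for d in range(1, n):
            ranks = np.array([base_rank] * (n - d) + [toward] * d, dtype=float)
            c = _rank_cv(ranks)
            if DEFAULT_Q1 < c <= DEFAULT_Q3:
                best = ranks
                break
            if best is None or abs(c - 0.2) < abs(_rank_cv(best) - 0.2):
                best = ranks
        ranks = best
    else:  # VARIABLE: symmetric spread around rank 2 where possible
        best = None
        for v in range(1, n):
            if base_rank == 2:
                lo = v // 2 + (v % 2)
                hi = v // 2
                ranks = np.array([2.0] * (n - lo - hi) + [1.0] * lo + [3.0] * hi)
            else:
                other = 4 - base_rank  # 1 <-> 3
                ranks = np.array([float(base_rank)] * (n - v) + [float(other)] * v)
            c = _rank_cv(ranks)
            if c > DEFAULT_Q3:
                best = ranks
                break
            best = ranks
        ranks = best
    rng.shuffle(ranks)
    return ranks


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate the genes x samples RPKM matrix and its planted truth.

    Per gene and group: an on/off mask realises the HK class; a base mode
    (low/moderate/high) and a variation status produce a per-sample rank
    template; each expressed cell draws from the template rank's log-normal
    mode times multiplicative noise, with the planted cancer fold change
    applied to up-regulated shared / cancer-associated genes.  Silent cells
    are exact zeros or intergenic-density draws.
    """
    rng = np.random.default_rng([_EXPR_STREAM, config.seed])
    ids = _gene_ids(config.n_genes)
    classes = _class_assignment(config)
    n_n, n_c = config.n_normal_samples, config.n_cancer_samples
    sample_ids = [f"N{i:02d}" for i in range(1, n_n + 1)] + \
                 [f"C{i:02d}" for i in range(1, n_c + 1)]
    samples = [
        SampleMeta(sid, NORMAL if sid.startswith("N") else CANCER,
                   int(rng.integers(8_000_000, 35_000_000)), 32)
        for sid in sample_ids
    ]
    mode_mu = np.array([m for m, _ in config.level_mixture])
    mode_sd = np.array([s for _, s in config.level_mixture])
    level_w = np.asarray(config.level_weights, dtype=float)
    level_w = level_w / level_w.sum()
    statuses = list(config.variation_fractions)
    status_p = np.array([config.variation_fractions[s] for s in statuses])
    ig_mu, ig_sd = config.intergenic_density
    fc = config.cancer_upregulation_log2fc

    values = np.zeros((config.n_genes, n_n + n_c))
    silent = np.zeros((config.n_genes, n_n + n_c), dtype=bool)
    rows = []

    for gi, (gid, cls) in enumerate(zip(ids, classes)):
        sil_n = np.zeros(n_n, dtype=bool)
        sil_c = np.zeros(n_c, dtype=bool)
        if cls in ("normal_unique", "tissue_specific"):
            sil_c = rng.random(n_c) < config.dropout_rate
            if not sil_c.any():
                sil_c[rng.integers(n_c)] = True
        if cls in ("cancer_associated", "tissue_specific"):
            sil_n = rng.random(n_n) < config.dropout_rate
            if not sil_n.any():
                sil_n[rng.integers(n_n)] = True

        upregulated = (cls in ("shared", "cancer_associated")
                       and fc > 0 and rng.random() < config.upregulated_fraction)
        gene_fc = fc if upregulated else 0.0

        rec = {"gene_id": gid, "hk_class": cls, "log2fc": gene_fc}
        for group, n_s, sil, col0 in ((NORMAL, n_n, sil_n, 0), (CANCER, n_c, sil_c, n_n)):
            mode = int(rng.choice(3, p=level_w))
            status = str(rng.choice(statuses, p=status_p))
            n_on = int((~sil).sum())
            # per-gene, per-group mode base values (shared across this group's cells)
            bases = np.exp(rng.normal(mode_mu, mode_sd))
            template = _rank_template(status, mode + 1, n_on, rng)
            cells = np.zeros(n_s)
            on_idx = np.flatnonzero(~sil)
            noise = np.exp(rng.normal(0.0, config.variation_sd, n_on))
            cells[on_idx] = bases[(template - 1).astype(int)] * noise
            if group == CANCER:
                cells[on_idx] *= 2.0 ** gene_fc
            off_idx = np.flatnonzero(sil)
            for oi in off_idx:
                if config.force_zero or rng.random() < config.silent_zero_fraction:
                    cells[oi] = 0.0
                else:
                    cells[oi] = float(rng.lognormal(ig_mu, ig_sd))
            values[gi, col0:col0 + n_s] = cells
            silent[gi, col0:col0 + n_s] = sil
            rec[f"level_mode_{group}"] = mode + 1
            rec[f"variation_{group}"] = status
        rows.append(rec)

    matrix = ExpressionMatrix(pd.DataFrame(values, index=ids, columns=sample_ids), samples)
    truth = SimTruth(
        table=pd.DataFrame(rows).set_index("gene_id"),
        silent_mask=pd.DataFrame(silent, index=ids, columns=sample_ids),
    )
    return matrix, truth


def simulate_intergenic(config: SimConfig, n_regions: int) -> np.ndarray:
    """Expression-density draws for intergenic regions (the negative set)."""
    if n_regions <= 0:
        raise InvalidInputError("n_regions must be positive")
    rng = np.random.default_rng([_INTERGENIC_STREAM, config.seed])
    return rng.lognormal(*config.intergenic_density, size=n_regions)


def check_truth_consistency(truth: SimTruth) -> None:
    """Assert every planted class label matches its on/off mask (raises on
    the first inconsistent gene)."""
    mask = truth.silent_mask
    normal_cols = [c for c in mask.columns if c.startswith("N")]
    cancer_cols = [c for c in mask.columns if c.startswith("C")]
    for gid, cls in truth.table["hk_class"].items():
        sn = mask.loc[gid, normal_cols].to_numpy().any()
        sc = mask.loc[gid, cancer_cols].to_numpy().any()
        ok = {
            "shared": not sn and not sc,
            "normal_unique": not sn and sc,
            "cancer_associated": sn and not sc,
            "tissue_specific": sn and sc,
        }[cls]
        if not ok:
            raise AssertionError(f"{gid}: class {cls} inconsistent with mask "
                                 f"(silent_normal={sn}, silent_cancer={sc})")


def simulate_study(config: SimConfig, n_intergenic: int = 5_000) -> dict:
    """Convenience bundle: annotation, expression matrix, truth, negatives."""
    genes, _ = simulate_annotation(config)
    matrix, truth = simulate_expression(config)
    intergenic = simulate_intergenic(config, n_intergenic)
    return {"genes": genes, "matrix": matrix, "truth": truth, "intergenic": intergenic}
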