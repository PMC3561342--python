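"""End-to-end pipeline: thresholds -> HK catalog -> variation -> MDAD ->
clustering -> structure bias, with every stage result written as TSV.

Stages communicate through files so each subcommand is independently
testable and a run is resumable; ``run_all`` executes the whole chain on
either a simulated study or user-supplied inputs and writes a JSON manifest
recording the seed and every decided default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .background import per_sample_backgrounds, unified_background
from .catalog import build_catalog, catalog_accounting
from .cluster import cluster_samples
from .core import ExpressionMatrix, InvalidInputError
from .mdad import accumulated_ratio_table, mdad_table, mdad_test_summary
from .simulate import SimConfig, simulate_study
from .structure import class_bias, structure_table
from .trilevel import trilevel_table
from .variation import (DEFAULT_Q1, DEFAULT_Q3, assign_ranks, cv_table,
                        cv_thresholds, status_table, transition_matrix)

log = logging.getLogger("hkatlas")


@dataclass
class PipelineConfig:
    """Knobs for a full run; None paths mean "simulate the study"."""

    out_dir: str = "hkatlas_run"
    seed: int = 0
    n_intergenic: int = 5_000
    background_override: float | None = None
    kmedians_k: int = 3
    kmedians_transform_n: float = 1.0
    kmedians_distance_space: str = "transformed"
    kmedians_restarts: int = 0
    cv_quartiles_override: tuple[float, float] | None = None
    mdad_alpha: float = 0.05
    clustering_linkage: str = "average"
    minimal_intron_max_bp: int = 125
    large_intron_min_bp: int = 50_000
    sim: dict = field(default_factory=dict)  # SimConfig overrides


def run_all(config: PipelineConfig, matrix: ExpressionMatrix | None = None,
            genes=None, intergenic=None) -> Path:
    """Run every stage and write the report directory; returns its path.

    When *matrix* is None a synthetic study is generated from
    ``config.sim`` + ``config.seed``.  Deterministic under a fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: v for k, v in asdict(config).items()}}

    truth = None
    if matrix is None:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        study = simulate_study(sim_cfg, n_intergenic=config.n_intergenic)
        matrix, genes, intergenic, truth = (study["matrix"], study["genes"],
                                            study["intergenic"], study["truth"])
        truth.table.to_csv(out / "truth.tsv", sep="\t")
    if intergenic is None:
        raise InvalidInputError("an intergenic negative set is required")

    # 1. background thresholds
    log.info("stage background")
    per_sample = per_sample_backgrounds(matrix, intergenic)
    background = (config.background_override if config.background_override is not None
                  else unified_background(per_sample.values()))
    pd.DataFrame({"sample_id": list(per_sample), "threshold": list(per_sample.values())}) \
        .to_csv(out / "background_thresholds.tsv", sep="\t", index=False)
    manifest["background_threshold"] = background

    # 2. HK catalog + accounting
    log.info("stage hk catalog")
    cat = build_catalog(matrix, background)
    cat.to_frame().to_csv(out / "hk_catalog.tsv", sep="\t")
    accounting = catalog_accounting(cat, total_loci=len(matrix.gene_ids))
    accounting.to_csv(out / "hk_accounting.tsv", sep="\t")

    # 3. tri-level thresholds (unified over the normal group, the control)
    log.info("stage trilevel")
    tri, (low, high) = trilevel_table(
        matrix, background, k=config.kmedians_k, n=config.kmedians_transform_n,
        distance_space=config.kmedians_distance_space, seed=config.seed,
        max_restarts=config.kmedians_restarts)
    tri.to_csv(out / "trilevel_thresholds.tsv", sep="\t")
    manifest["unified_low"], manifest["unified_high"] = low, high

    # 4. ranks, CV, statuses, transitions
    log.info("stage variation")
    ranks = assign_ranks(matrix.values, low, high, background)
    normal_cols = matrix.group_columns("normal")
    cancer_cols = matrix.group_columns("cancer")
    cv_normal = cv_table(ranks.loc[sorted(cat.normal_hk), normal_cols])
    cv_cancer = cv_table(ranks.loc[sorted(cat.cancer_hk), cancer_cols])
    if config.cv_quartiles_override is not None:
        q1, q3 = config.cv_quartiles_override
    else:
        q1, q3 = cv_thresholds(cv_normal.to_numpy())
    manifest["cv_q1"], manifest["cv_q3"] = q1, q3
    status_normal = status_table(cv_normal, q1, q3)
    status_cancer = status_table(cv_cancer, q1, q3)
    pd.DataFrame({"cv_normal": cv_normal, "status_normal": status_normal}) \
        .to_csv(out / "cv_normal.tsv", sep="\t")
    pd.DataFrame({"cv_cancer": cv_cancer, "status_cancer": status_cancer}) \
        .to_csv(out / "cv_cancer.tsv", sep="\t")
    shared = sorted(cat.shared)
    trans = transition_matrix(status_normal.loc[shared], status_cancer.loc[shared])
    trans.to_csv(out / "cv_transitions.tsv", sep="\t")

    # 5. MDAD statistics for shared and cancer-associated HK genes
    log.info("stage mdad")
    for label, genes_of_class, statuses in (
        ("shared", shared, status_normal),
        ("cancer_associated", sorted(cat.cancer_associated), status_cancer),
    ):
        table = mdad_table(matrix, genes_of_class)
        table.to_csv(out / f"mdad_{label}.tsv", sep="\t")
        summary = mdad_test_summary(table, statuses, alpha=config.mdad_alpha)
        summary.to_csv(out / f"mdad_{label}_tests.tsv", sep="\t")
        acc = accumulated_ratio_table(table, statuses)
        acc.to_csv(out / f"ratio_accumulation_{label}.tsv", sep="\t")

    # 6. sample clustering
    log.info("stage cluster")
    tree, partition, purity = cluster_samples(matrix, linkage=config.clustering_linkage)
    (out / "profile_tree.nwk").write_text(tree.to_newick() + "\n")
    pd.DataFrame({"sample_id": list(partition), "cluster": list(partition.values())}) \
        .to_csv(out / "cluster_partition.tsv", sep="\t", index=False)
    manifest["two_group_purity"] = purity

    # 7. structure bias
    if genes is not None:
        log.info("stage structure")
        struct = structure_table(genes,
                                 minimal_intron_max_bp=config.minimal_intron_max_bp,
                                 large_intron_min_bp=config.large_intron_min_bp)
        struct.to_csv(out / "gene_structure.tsv", sep="\t")
        bias = class_bias(struct, cat, alpha=config.mdad_alpha)
        bias.to_csv(out / "structure_bias.tsv", sep="\t")

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("run complete: %s", out)
    return out
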