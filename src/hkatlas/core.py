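"""Core data model: samples, expression matrices, gene models, RPKM.

The central object is :class:`ExpressionMatrix`, a genes x samples table of
non-negative RPKM values together with per-sample metadata (group label,
library size).  Expression is quantified as reads per kilobase of coding
sequence per million mapped reads (RPKM), and a gene's expression is the sum
over its isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NORMAL = "normal"
CANCER = "cancer"
GROUPS = (NORMAL, CANCER)


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (2.5 -> 3, 1.055 -> 1.06 at 2 digits).

    Report tables use this convention; Python's built-in ``round`` rounds
    halves to even and is additionally subject to binary representation of
    the input, so 1.055 would round down.
    """
    import decimal

    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-Seq sample.

    Parameters
    ----------
    sample_id : unique sample name.
    group : physiological condition, ``"normal"`` or ``"cancer"``.
    total_mapped_reads : library size (mapped reads), > 0.
    read_length : nominal read length in bp (informational only).
    """

    sample_id: str
    group: str
    total_mapped_reads: int
    read_length: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.total_mapped_reads <= 0:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: total_mapped_reads must be positive"
            )


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values (RPKM).

    ``values`` is a pandas DataFrame indexed by gene id with one column per
    sample, aligned with ``samples``.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        ids = [s.sample_id for s in self.samples]
        if cols != ids:
            raise InvalidInputError(
                f"sample sheet / matrix column mismatch: {ids} vs {cols}"
            )
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate sample ids")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate gene ids: {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise InvalidInputError("expression values must be numeric")
        if np.isnan(arr).any():
            raise InvalidInputError("expression values contain NaN")
        if (arr < 0).any():
            raise InvalidInputError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_columns(self, group: str) -> list[str]:
        """Sample ids belonging to *group* (``normal`` or ``cancer``)."""
        if group not in GROUPS:
            raise InvalidInputError(f"unknown group {group!r}")
        return [s.sample_id for s in self.samples if s.group == group]

    def group_values(self, group: str) -> pd.DataFrame:
        cols = self.group_columns(group)
        if not cols:
            raise InvalidInputError(f"no samples in group {group!r}")
        return self.values[cols]

    def with_swapped_groups(self) -> "ExpressionMatrix":
        """Return a copy with normal/cancer labels exchanged (for symmetry checks)."""
        swapped = [
            SampleMeta(s.sample_id, CANCER if s.group == NORMAL else NORMAL,
                       s.total_mapped_reads, s.read_length)
            for s in self.samples
        ]
        return ExpressionMatrix(self.values.copy(), swapped)


@dataclass
class GeneModel:
    """Gene annotation: one or more transcripts with exon structure.

    Coordinates are 0-based half-open throughout.  ``exons`` maps
    transcript id -> list of (start, end) intervals sorted by start.
    ``cds_length_bp`` maps transcript id -> coding length in bp.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: dict[str, list[tuple[int, int]]]
    cds_length_bp: dict[str, int]
    sequence_gc: float = 0.5

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"{self.gene_id}: strand must be + or -")
        if not 0.0 <= self.sequence_gc <= 1.0:
            raise InvalidInputError(f"{self.gene_id}: sequence_gc outside [0, 1]")
        for tx, ivals in self.exons.items():
            if not ivals:
                raise InvalidInputError(f"{self.gene_id}/{tx}: transcript with zero exons")
            for s, e in ivals:
                if e <= s:
                    raise InvalidInputError(f"{self.gene_id}/{tx}: empty exon ({s}, {e})")
        for tx in self.cds_length_bp:
            if tx not in self.exons:
                raise InvalidInputError(f"{self.gene_id}: CDS length for unknown transcript {tx}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.exons)

    @property
    def gene_span_bp(self) -> int:
        starts = [iv[0][0] for iv in self.exons.values()]
        ends = [iv[-1][1] for iv in self.exons.values()]
        return max(ends) - min(starts)

    def representative_transcript(self) -> str:
        """Transcript with the longest CDS (ties: lexicographically first id)."""
        return min(self.exons, key=lambda t: (-self.cds_length_bp.get(t, 0), t))


def compute_rpkm(read_count: float, cds_length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of coding sequence per million mapped reads.

    RPKM = read_count / (cds_length_bp / 1e3) / (total_mapped_reads / 1e6).
    """
    if cds_length_bp <= 0:
        raise InvalidInputError(f"cds_length_bp must be positive, got {cds_length_bp}")
    if total_mapped_reads <= 0:
        raise InvalidInputError(f"total_mapped_reads must be positive, got {total_mapped_reads}")
    if read_count < 0:
        raise InvalidInputError(f"read_count must be non-negative, got {read_count}")
    return read_count / (cds_length_bp / 1e3) / (total_mapped_reads / 1e6)


def aggregate_isoforms(
    transcript_expression: Mapping[str, float],
    gene_map: Mapping[str, str],
) -> dict[str, float]:
    """Sum isoform expression to the gene level.

    A gene's expression is the sum of the expression of all of its isoforms;
    the grand total is conserved.
    """
    out: dict[str, float] = {}
    for tx, value in transcript_expression.items():
        if tx not in gene_map:
            raise InvalidInputError(f"transcript {tx!r} missing from gene map")
        if value < 0:
            raise InvalidInputError(f"transcript {tx!r}: negative expression {value}")
        gene = gene_map[tx]
        out[gene] = out.get(gene, 0.0) + float(value)
    return out
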