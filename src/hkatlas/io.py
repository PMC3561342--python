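"""Plain-text I/O: expression TSV, sample sheets, BED12 and minimal GTF.

All tabular interchange is tab-separated text.  The expression matrix has
gene ids in the first column and one column per sample; group labels and
library sizes travel in a separate sample sheet
(``sample_id<TAB>group<TAB>total_mapped_reads[<TAB>read_length]``).
Coordinates are 0-based half-open internally; BED input is native, GTF input
(1-based closed) is converted on read.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneModel, InvalidInputError, SampleMeta


class ParseError(ValueError):
    """A malformed input file; the message carries the offending line number."""


# ---------------------------------------------------------------- expression


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "total_mapped_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                group=row["group"],
                total_mapped_reads=int(row["total_mapped_reads"]),
                read_length=int(row.get("read_length", 0) or 0),
            )
        )
    return metas


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "total_mapped_reads": [s.total_mapped_reads for s in samples],
            "read_length": [s.read_length for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path, samples: Sequence[SampleMeta]) -> ExpressionMatrix:
    """Read a genes x samples TSV and attach sample metadata.

    Raises :class:`ParseError` with a line number for ragged rows,
    non-numeric cells, negative values or duplicate gene ids.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: expected gene id column plus sample columns")
        sample_ids = header[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})"
                )
            gid = parts[0]
            if gid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
            if any(v < 0 for v in vals):
                raise ParseError(f"{path}:{lineno}: negative expression value")
            genes.append(gid)
            rows.append(vals)
    df = pd.DataFrame(rows, index=genes, columns=sample_ids)
    return ExpressionMatrix(df, list(samples))


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix with 12 significant digits (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        arr = matrix.values.to_numpy()
        for gid, row in zip(matrix.gene_ids, arr):
            # repr(float) is the shortest lossless representation
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------- annotation


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    """One BED12 line per transcript; the gene id rides in column 13 and the
    GC fraction in column 14 (BED-with-extras, tab-separated)."""
    with open(path, "w") as fh:
        for g in genes:
            for tx in g.transcript_ids:
                ivals = g.exons[tx]
                start = ivals[0][0]
                end = ivals[-1][1]
                sizes = ",".join(str(e - s) for s, e in ivals)
                starts = ",".join(str(s - start) for s, e in ivals)
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            str(start),
                            str(end),
                            tx,
                            str(g.cds_length_bp.get(tx, 0)),
                            g.strand,
                            str(start),
                            str(end),
                            "0",
                            str(len(ivals)),
                            sizes,
                            starts,
                            g.gene_id,
                            format(g.sequence_gc, ".6g"),
                        ]
                    )
                    + "\n"
                )


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read the BED12(+2) annotation written by :func:`write_bed12`.

    Plain 12-column BED is also accepted; then the transcript name doubles as
    gene id and GC defaults to 0.5.  The BED score column carries the CDS
    length in bp (sum of exon sizes when 0).
    """
    path = Path(path)
    per_gene: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected >=12 BED columns, got {len(f)}")
            try:
                chrom, start, tx = f[0], int(f[1]), f[3]
                cds = int(float(f[4]))
                strand = f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED12 field ({exc})") from exc
            if len(sizes) != n_blocks or len(offs) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            gene_id = f[12] if len(f) > 12 else tx
            gc = float(f[13]) if len(f) > 13 else 0.5
            ivals = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            if cds == 0:
                cds = sum(s for s in sizes)
            rec = per_gene.get(gene_id)
            if rec is None:
                rec = {"chrom": chrom, "strand": strand, "gc": gc, "exons": {}, "cds": {}}
                per_gene[gene_id] = rec
                order.append(gene_id)
            rec["exons"][tx] = ivals
            rec["cds"][tx] = cds
    return [
        GeneModel(
            gene_id=gid,
            chrom=per_gene[gid]["chrom"],
            strand=per_gene[gid]["strand"],
            exons=per_gene[gid]["exons"],
            cds_length_bp=per_gene[gid]["cds"],
            sequence_gc=per_gene[gid]["gc"],
        )
        for gid in order
    ]


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read a minimal GTF subset: ``exon`` and ``CDS`` features carrying
    ``gene_id`` and ``transcript_id`` attributes.  1-based closed coordinates
    are converted to 0-based half-open."""
    path = Path(path)
    per_gene: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(f)}")
            chrom, _, feature, start, end, _, strand, _, attrs = f
            if feature not in ("exon", "CDS"):
                continue
            try:
                s0, e0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates ({exc})") from exc
            tags = {}
            for item in attrs.rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                tags[key] = val.strip().strip('"')
            gid = tags.get("gene_id")
            tx = tags.get("transcript_id")
            if not gid or not tx:
                raise ParseError(f"{path}:{lineno}: missing gene_id/transcript_id attribute")
            rec = per_gene.get(gid)
            if rec is None:
                rec = {"chrom": chrom, "strand": strand, "exons": {}, "cds": {}}
                per_gene[gid] = rec
                order.append(gid)
            if feature == "exon":
                rec["exons"].setdefault(tx, []).append((s0, e0))
            else:
                rec["cds"][tx] = rec["cds"].get(tx, 0) + (e0 - s0)
    out = []
    for gid in order:
        rec = per_gene[gid]
        exons = {tx: sorted(iv) for tx, iv in rec["exons"].items()}
        cds = {tx: rec["cds"].get(tx, sum(e - s for s, e in iv)) for tx, iv in exons.items()}
        out.append(
            GeneModel(gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                      exons=exons, cds_length_bp=cds)
        )
    return out
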