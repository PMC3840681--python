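"""Readers and writers for the standard formats, plus sequencing-summary arithmetic.

Annotations come in as GFF3 (via gffutils) or BED12; DSB events as BED3/BED4;
expression tables, recombination maps and result tables as UTF-8 TSV with a
header row and '.' decimals.  Internally everything is 0-based half-open;
GFF3's 1-based closed coordinates are converted at this boundary only.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

from .types import (
    Chromosome,
    DSBEventSet,
    ExpressionTable,
    Gene,
    GenomeAnnotation,
    RecombinationMap,
    SampleMeta,
    ValidationError,
    ChromClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "percent_mapped",
    "gff3_to_internal",
    "internal_to_gff3",
    "infer_chrom_class",
    "read_annotation",
    "write_annotation_gff3",
    "read_expression",
    "write_expression",
    "read_recombination_map",
    "write_recombination_map",
    "read_dsb_bed",
    "write_dsb_bed",
    "read_fasta",
    "write_fasta",
    "write_table",
]


# ---------------------------------------------------------------------------
# summary arithmetic

def percent_mapped(gross_reads: int, mapped_reads: int) -> float:
    """Percentage of gross reads that mapped, 100 × mapped / gross.

    Rounding to a printed precision is left to the caller.
    """
    if gross_reads <= 0:
        raise ValidationError("percent_mapped undefined for gross_reads <= 0")
    if not (0 <= mapped_reads <= gross_reads):
        raise ValidationError("require 0 <= mapped_reads <= gross_reads")
    return 100.0 * mapped_reads / gross_reads


# ---------------------------------------------------------------------------
# coordinate conventions

def gff3_to_internal(start: int, end: int) -> tuple[int, int]:
    """GFF3 1-based closed -> 0-based half-open."""
    return start - 1, end


def internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based closed."""
    return start + 1, end


def infer_chrom_class(name: str) -> ChromClass:
    lowered = name.lower()
    if lowered in {"chrx", "x"} or lowered.endswith("chrx"):
        return "X"
    if "chru" in lowered or lowered.startswith(("chrun", "un_")) or "random" in lowered:
        return "unplaced"
    return "autosome"


def _chrom_class_for(
    name: str, chrom_classes: Optional[Mapping[str, str]]
) -> ChromClass:
    if chrom_classes is not None and name in chrom_classes:
        cls = chrom_classes[name]
        if cls not in ("X", "autosome", "unplaced"):
            raise ValidationError(f"unknown chromosome class {cls!r} for {name}")
        return cls  # type: ignore[return-value]
    return infer_chrom_class(name)


# ---------------------------------------------------------------------------
# annotations

def read_annotation(
    path: str | Path,
    format: str = "gff3",
    chrom_classes: Optional[Mapping[str, str]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> GenomeAnnotation:
    """Read a gene annotation from GFF3 or BED12.

    Chromosome lengths are taken from ``chrom_lengths`` when given, else from
    GFF3 ``##sequence-region`` directives, else from the maximal gene end on
    each chromosome.  Genes beyond a known chromosome length raise a
    validation error.
    """
    fmt = format.lower()
    if fmt == "gff3":
        genes, seq_regions = _read_gff3_genes(Path(path))
    elif fmt == "bed12":
        genes = _read_bed12_genes(Path(path))
        seq_regions = {}
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    if not genes:
        warnings.warn(f"annotation {path} contains no genes", stacklevel=2)

    lengths: dict[str, int] = dict(seq_regions)
    if chrom_lengths:
        lengths.update(chrom_lengths)
    for g in genes:
        if g["chrom"] not in lengths:
            lengths[g["chrom"]] = 0
        if g["end"] > lengths[g["chrom"]] and g["chrom"] not in (chrom_lengths or {}):
            if g["chrom"] in seq_regions:
                raise ValidationError(
                    f"gene {g['gene_id']} exceeds declared length of {g['chrom']}"
                )
            lengths[g["chrom"]] = g["end"]

    chroms = [
        Chromosome(name, length, _chrom_class_for(name, chrom_classes))
        for name, length in sorted(lengths.items())
        if length > 0
    ]
    gene_objs = [Gene(**g) for g in genes]
    return GenomeAnnotation(chromosomes=chroms, genes=gene_objs)


def _read_gff3_genes(path: Path) -> tuple[list[dict], dict[str, int]]:
    seq_regions: dict[str, int] = {}
    has_features = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    seq_regions[parts[1]] = int(parts[3])
            elif line and not line.startswith("#"):
                has_features = True
    if not has_features:  # gffutils cannot build a db from a feature-less file
        return [], seq_regions

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise ValidationError(f"cannot parse GFF3 {path}: {exc}") from exc

    genes: list[dict] = []
    for feat in db.features_of_type("gene"):
        start, end = gff3_to_internal(feat.start, feat.end)
        exon_total = 0
        for exon in db.children(feat, featuretype="exon"):
            es, ee = gff3_to_internal(exon.start, exon.end)
            exon_total += ee - es
        if "transcript_length" in feat.attributes:
            tlen = int(feat.attributes["transcript_length"][0])
        elif exon_total > 0:
            tlen = exon_total
        else:
            tlen = end - start
        genes.append(
            dict(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand if feat.strand in "+-" else ".",
                transcript_length=tlen,
            )
        )
    return genes, seq_regions


def _read_bed12_genes(path: Path) -> list[dict]:
    genes: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValidationError(
                    f"{path}:{lineno}: BED12 needs 12 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5] if fields[5] in "+-" else "."
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed record") from exc
            genes.append(
                dict(
                    gene_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    transcript_length=sum(sizes),
                )
            )
    return genes


def write_annotation_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write genes as GFF3 with sequence-region directives.

    The exonic length is preserved in a ``transcript_length`` attribute so
    the annotation round-trips without exon features.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in annotation.chromosomes:
            fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
        for g in annotation.genes:
            start, end = internal_to_gff3(g.start, g.end)
            fh.write(
                f"{g.chrom}\tmeiolandscape\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};transcript_length={g.transcript_length}\n"
            )


# ---------------------------------------------------------------------------
# expression tables (long TSV)

_EXPR_COLUMNS = [
    "gene_id",
    "sample_id",
    "condition",
    "genotype",
    "maternal_strain",
    "sample_gross_reads",
    "sample_mapped_reads",
    "fpkm",
    "mapped_reads",
]


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    """Write an expression table as long TSV; absent cells are not written."""
    rows = []
    for s in table.samples:
        fp = table.fpkm[s.sample_id]
        rd = table.reads[s.sample_id]
        present = fp.notna()
        for gene_id in fp.index[present]:
            rows.append(
                (
                    gene_id,
                    s.sample_id,
                    s.condition,
                    s.genotype,
                    s.maternal_strain if s.maternal_strain is not None else ".",
                    s.gross_reads,
                    s.mapped_reads,
                    repr(float(fp[gene_id])),
                    int(rd[gene_id]),
                )
            )
    df = pd.DataFrame(rows, columns=_EXPR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a long-TSV expression table written by :func:`write_expression`.

    Cells not present in the file are kept as NaN (absent, distinct from
    zero); the number of absent cells is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing expression columns {missing}")

    fpkm_vals = np.empty(len(df))
    for i, raw in enumerate(df["fpkm"]):
        try:
            fpkm_vals[i] = float(raw)
        except ValueError:
            raise ValidationError(
                f"{path}: non-numeric FPKM {raw!r} at gene "
                f"{df['gene_id'].iloc[i]}, sample {df['sample_id'].iloc[i]}"
            ) from None
    if (fpkm_vals < 0).any():
        bad = df["gene_id"].iloc[int(np.argmax(fpkm_vals < 0))]
        raise ValidationError(f"{path}: negative FPKM at gene {bad}")
    df = df.assign(fpkm=fpkm_vals, mapped_reads=df["mapped_reads"].astype(int))

    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        first = grp.iloc[0]
        samples.append(
            SampleMeta(
                sample_id=sid,
                condition=first["condition"],
                genotype=first["genotype"],
                maternal_strain=(
                    None if first["maternal_strain"] == "." else first["maternal_strain"]
                ),
                gross_reads=int(first["sample_gross_reads"]),
                mapped_reads=int(first["sample_mapped_reads"]),
            )
        )
    fpkm = df.pivot(index="gene_id", columns="sample_id", values="fpkm")
    reads = df.pivot(index="gene_id", columns="sample_id", values="mapped_reads")
    order = [s.sample_id for s in samples]
    fpkm, reads = fpkm[order], reads[order]
    fpkm.columns.name = reads.columns.name = None
    table = ExpressionTable(samples=samples, fpkm=fpkm, reads=reads)
    n_absent = table.n_absent()
    if n_absent:
        logger.info("expression table %s: %d absent cells", path, n_absent)
    return table


# ---------------------------------------------------------------------------
# recombination maps and DSB events

def write_recombination_map(rmap: RecombinationMap, path: str | Path) -> None:
    out = rmap.windows.rename(columns={"rate": "cM_per_Mb"})
    out.to_csv(path, sep="\t", index=False)


def read_recombination_map(path: str | Path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t")
    if "cM_per_Mb" in df.columns:
        df = df.rename(columns={"cM_per_Mb": "rate"})
    return RecombinationMap(windows=df[["chrom", "start", "end", "rate"]])


def write_dsb_bed(events: DSBEventSet, path: str | Path) -> None:
    """BED3, or BED4 with the category in the name column when present."""
    cols = ["chrom", "start", "end"]
    df = events.events
    if "category" in df.columns:
        df = df[cols + ["category"]]
    else:
        df = df[cols]
    df.to_csv(path, sep="\t", index=False, header=False)


def read_dsb_bed(path: str | Path, max_width: int = 500) -> DSBEventSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: BED needs >= 3 fields")
            try:
                row = {"chrom": fields[0], "start": int(fields[1]), "end": int(fields[2])}
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed record") from exc
            if len(fields) >= 4:
                row["category"] = fields[3]
            rows.append(row)
    return DSBEventSet(events=pd.DataFrame(rows), max_width=max_width)


# ---------------------------------------------------------------------------
# FASTA and generic tables

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Uniform TSV writer for result tables."""
    df.to_csv(path, sep="\t", index=index)
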