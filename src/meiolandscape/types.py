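"""Core domain containers shared by every analysis stage.

All genomic coordinates are 0-based, half-open ``[start, end)``.  Format
readers (GFF3 is 1-based, closed) convert at the boundary, never internally.
Strand is carried on genes but ignored by the window, clustering and DSB
analyses, which are strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

ChromClass = Literal["X", "autosome", "unplaced"]

__all__ = [
    "Gene",
    "Chromosome",
    "GenomeAnnotation",
    "SampleMeta",
    "ExpressionTable",
    "RecombinationMap",
    "DSBEventSet",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


@dataclass(frozen=True)
class Gene:
    """A gene interval with the exonic (transcript) length used for FPKM×length.

    ``transcript_length`` is the summed exonic length and may legitimately be
    shorter than, equal to, or (for multi-isoform entries) unrelated to the
    genomic footprint ``end - start``; it only has to be positive.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    transcript_length: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.transcript_length <= 0:
            raise ValidationError(
                f"gene {self.gene_id}: transcript_length must be > 0"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    chrom_class: ChromClass = "autosome"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"chromosome {self.name}: length must be > 0")
        if self.chrom_class not in ("X", "autosome", "unplaced"):
            raise ValidationError(
                f"chromosome {self.name}: unknown class {self.chrom_class!r}"
            )


@dataclass
class GenomeAnnotation:
    """Chromosome backbone plus genes, sorted by (chrom, start, end, gene_id)."""

    chromosomes: list[Chromosome]
    genes: list[Gene]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        self._by_name = {c.name: c for c in self.chromosomes}
        for g in self.genes:
            chrom = self._by_name.get(g.chrom)
            if chrom is None:
                raise ValidationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > chrom.length:
                raise ValidationError(
                    f"gene {g.gene_id}: [{g.start}, {g.end}) exceeds "
                    f"{chrom.name} length {chrom.length}"
                )
        self.genes = sorted(
            self.genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)
        )

    def chromosome(self, name: str) -> Chromosome:
        return self._by_name[name]

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom_class(self, name: str) -> ChromClass:
        return self._by_name[name].chrom_class

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def gene_frame(self) -> pd.DataFrame:
        """Genes as a DataFrame indexed by gene_id (sorted gene order)."""
        return pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "transcript_length": [g.transcript_length for g in self.genes],
            },
            index=pd.Index([g.gene_id for g in self.genes], name="gene_id"),
        )


@dataclass(frozen=True)
class SampleMeta:
    """Per-library metadata mirroring a sequencing summary row."""

    sample_id: str
    condition: Literal["Early", "Late"]
    genotype: str
    maternal_strain: Optional[str] = None
    gross_reads: int = 0
    mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("Early", "Late"):
            raise ValidationError(f"sample {self.sample_id}: bad condition")
        if self.mapped_reads > self.gross_reads:
            raise ValidationError(
                f"sample {self.sample_id}: mapped_reads > gross_reads"
            )


class ExpressionTable:
    """Gene × sample FPKM and mapped-read counts.

    Missing cells are NaN and mean *absent* (no measurement), which is
    distinct from an explicit zero; threshold operations treat absent as
    "not expressed" but report how many cells were absent.
    """

    def __init__(
        self,
        samples: Sequence[SampleMeta],
        fpkm: pd.DataFrame,
        reads: pd.DataFrame,
    ) -> None:
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids")
        if list(fpkm.columns) != ids or list(reads.columns) != ids:
            raise ValidationError("fpkm/reads columns must match sample ids in order")
        if not fpkm.index.equals(reads.index):
            raise ValidationError("fpkm and reads must share the gene index")
        vals = fpkm.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0 or not np.all(
            np.isfinite(vals[~np.isnan(vals)])
        ):
            raise ValidationError("FPKM values must be finite and non-negative")
        if np.nanmin(reads.to_numpy(dtype=float), initial=0.0) < 0:
            raise ValidationError("read counts must be non-negative")
        self.samples = list(samples)
        self.fpkm = fpkm
        self.reads = reads

    @property
    def gene_ids(self) -> pd.Index:
        return self.fpkm.index

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def samples_in(
        self, condition: Optional[str] = None, genotype: Optional[str] = None
    ) -> list[SampleMeta]:
        out = []
        for s in self.samples:
            if condition is not None and s.condition != condition:
                continue
            if genotype is not None and s.genotype != genotype:
                continue
            out.append(s)
        return out

    def condition_mean_fpkm(self, condition: str) -> pd.Series:
        cols = [s.sample_id for s in self.samples_in(condition)]
        if not cols:
            raise KeyError(f"no samples in condition {condition!r}")
        return self.fpkm[cols].mean(axis=1)

    def n_absent(self) -> int:
        return int(self.fpkm.isna().to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.fpkm.equals(other.fpkm)
            and self.reads.equals(other.reads)
        )


@dataclass
class RecombinationMap:
    """Fixed, sorted, non-overlapping windows with a rate in cM/Mb."""

    windows: pd.DataFrame  # columns: chrom, start, end, rate

    def __post_init__(self) -> None:
        w = self.windows
        required = ["chrom", "start", "end", "rate"]
        if list(w.columns[:4]) != required:
            raise ValidationError(f"recombination map needs columns {required}")
        if (w["rate"] < 0).any():
            raise ValidationError("recombination rates must be >= 0")
        if (w["end"] <= w["start"]).any():
            raise ValidationError("windows must have end > start")
        for chrom, grp in w.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                raise ValidationError(f"{chrom}: windows not sorted")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{chrom}: overlapping windows")

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class DSBEventSet:
    """Localized recombination-initiation events, each at most ``max_width`` bp."""

    events: pd.DataFrame  # columns: chrom, start, end [, category]
    max_width: int = 500

    def __post_init__(self) -> None:
        e = self.events
        if not {"chrom", "start", "end"}.issubset(e.columns):
            raise ValidationError("events need chrom, start, end columns")
        widths = e["end"] - e["start"]
        if (widths <= 0).any():
            raise ValidationError("events must have end > start")
        if (widths > self.max_width).any():
            raise ValidationError(f"event wider than {self.max_width} bp")

    def validate_bounds(self, annotation: GenomeAnnotation) -> None:
        for chrom, grp in self.events.groupby("chrom", sort=False):
            length = annotation.chromosome(chrom).length
            if (grp["start"] < 0).any() or (grp["end"] > length).any():
                raise ValidationError(f"event outside {chrom} bounds")

    @property
    def midpoints(self) -> pd.DataFrame:
        mid = (self.events["start"] + self.events["end"]) // 2
        return pd.DataFrame({"chrom": self.events["chrom"], "pos": mid})

    def __len__(self) -> int:
        return len(self.events)
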