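"""Staged filter cascade for candidate novel transcripts.

Candidates from an upstream assembler are reduced in a fixed order:
(1) detected in at least ``min_samples`` samples, (2) expressed above
``min_fpkm`` in at least one sample, (3) longer than ``min_length`` bp with
an acceptably low repetitive fraction and splice-junction support.  The
cascade is monotone by construction — each stage filters the previous
stage's survivors — and the final manual-curation step applied in practice
(visual inspection of exon–intron structure) is outside its scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import ValidationError

__all__ = ["NovelCandidate", "CascadeResult", "filter_cascade"]

STAGES = ("input", "detected_in_min_samples", "fpkm_above_min", "structure")


@dataclass(frozen=True)
class NovelCandidate:
    id: str
    chrom: str
    start: int
    end: int
    fpkm: tuple[float, ...]  # one value per sample
    repetitive_fraction: float = 0.0
    splice_junction_support: bool = True
    overlaps_annotation: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"candidate {self.id}: start >= end")
        if not 0.0 <= self.repetitive_fraction <= 1.0:
            raise ValidationError(
                f"candidate {self.id}: repetitive_fraction outside [0, 1]"
            )
        if any(f < 0 for f in self.fpkm):
            raise ValidationError(f"candidate {self.id}: negative FPKM")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CascadeResult:
    survivors: dict[str, list[NovelCandidate]]
    counts: dict[str, int]

    def surviving_ids(self, stage: str) -> list[str]:
        return [c.id for c in self.survivors[stage]]


def filter_cascade(
    candidates: Sequence[NovelCandidate],
    min_samples: int = 2,
    min_fpkm: float = 1.0,
    min_length: int = 300,
    max_repetitive: float = 0.5,
    require_junctions: bool = True,
    detected_min_fpkm: float = 0.0,
) -> CascadeResult:
    """Run the three-stage novel-transcript filter.

    "Detected" at stage 1 means FPKM strictly above ``detected_min_fpkm``
    (0 by default).  Stage 2 keeps candidates with FPKM > ``min_fpkm`` in at
    least one sample; stage 3 requires length > ``min_length``,
    repetitive_fraction <= ``max_repetitive`` and, when ``require_junctions``,
    splice-junction support.  Returns survivors and counts at every stage;
    empty input yields zero counts throughout.
    """
    stage_sets: dict[str, list[NovelCandidate]] = {STAGES[0]: list(candidates)}

    stage1 = [
        c
        for c in stage_sets[STAGES[0]]
        if sum(f > detected_min_fpkm for f in c.fpkm) >= min_samples
    ]
    stage_sets[STAGES[1]] = stage1

    stage2 = [c for c in stage1 if any(f > min_fpkm for f in c.fpkm)]
    stage_sets[STAGES[2]] = stage2

    stage3 = [
        c
        for c in stage2
        if c.length > min_length
        and c.repetitive_fraction <= max_repetitive
        and (c.splice_junction_support or not require_junctions)
    ]
    stage_sets[STAGES[3]] = stage3

    return CascadeResult(
        survivors=stage_sets,
        counts={name: len(group) for name, group in stage_sets.items()},
    )
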