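"""Wald–Wolfowitz runs test on gene order and cluster-size summaries.

Genes are ordered along each chromosome by (start, end, gene_id); overlapping
genes each contribute one label in that order.  By default runs are counted
within chromosomes and the normal-approximation moments are summed across
them, so chromosome junctions never create artificial runs; a genome-as-one-
sequence mode is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionTable, GenomeAnnotation, ValidationError

__all__ = ["RunsTestResult", "runs_test", "mean_cluster_size", "activity_label_sequences"]


@dataclass(frozen=True)
class RunsTestResult:
    n_runs: int
    n_active: int
    n_inactive: int
    expected_runs: float
    variance_runs: float
    z: Optional[float]
    p: Optional[float]
    mean_active_cluster_size: Optional[float]
    note: Optional[str] = None


def _chromosome_terms(labels: np.ndarray) -> tuple[int, int, int, float, float]:
    """Runs count and Wald–Wolfowitz moments for one label sequence."""
    n = labels.size
    if n == 0:
        return 0, 0, 0, 0.0, 0.0
    n1 = int(labels.sum())
    n2 = n - n1
    runs = 1 + int(np.count_nonzero(labels[1:] != labels[:-1]))
    if n < 2 or n1 == 0 or n2 == 0:
        return runs, n1, n2, float(runs), 0.0
    e = 2.0 * n1 * n2 / n + 1.0
    v = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    return runs, n1, n2, e, max(v, 0.0)


def runs_test(
    sequences: Sequence[Sequence[bool]] | Mapping[str, Sequence[bool]],
    pooled: str = "per-chromosome",
) -> RunsTestResult:
    """Test whether active/inactive labels are randomly ordered.

    ``sequences`` is one label sequence per chromosome.  ``pooled`` selects
    how chromosomes combine: ``"per-chromosome"`` counts runs within each and
    sums counts and moments; ``"genome"`` concatenates everything into one
    sequence.  Clustering shows up as fewer runs than expected (z < 0);
    the p-value is two-sided.
    """
    if isinstance(sequences, Mapping):
        seqs = [np.asarray(s, dtype=bool) for s in sequences.values()]
    else:
        seqs = [np.asarray(s, dtype=bool) for s in sequences]
    seqs = [s for s in seqs if s.size > 0]
    total_n = sum(s.size for s in seqs)
    if total_n < 2:
        raise ValidationError("runs test needs at least 2 labels")

    if pooled == "genome":
        seqs = [np.concatenate(seqs)]
    elif pooled != "per-chromosome":
        raise ValueError(f"unknown pooling mode {pooled!r}")

    runs = n1 = n2 = 0
    e_total = v_total = 0.0
    for s in seqs:
        r, c1, c2, e, v = _chromosome_terms(s)
        runs += r
        n1 += c1
        n2 += c2
        e_total += e
        v_total += v

    mean_size = mean_cluster_size_multi(seqs, True) if n1 > 0 else None

    if n1 == 0 or n2 == 0 or v_total <= 0:
        return RunsTestResult(
            n_runs=runs,
            n_active=n1,
            n_inactive=n2,
            expected_runs=e_total,
            variance_runs=v_total,
            z=None,
            p=None,
            mean_active_cluster_size=mean_size,
            note="z/p undefined: a label class is absent or variance is zero",
        )
    z = (runs - e_total) / np.sqrt(v_total)
    p = 2.0 * stats.norm.sf(abs(z))
    return RunsTestResult(
        n_runs=runs,
        n_active=n1,
        n_inactive=n2,
        expected_runs=e_total,
        variance_runs=v_total,
        z=float(z),
        p=float(min(p, 1.0)),
        mean_active_cluster_size=mean_size,
    )


def _run_lengths(labels: np.ndarray, target: bool) -> list[int]:
    lengths = []
    count = 0
    for lab in labels:
        if bool(lab) == target:
            count += 1
        elif count:
            lengths.append(count)
            count = 0
    if count:
        lengths.append(count)
    return lengths


def mean_cluster_size(labels: Sequence[bool], target_label: bool = True) -> float:
    """Mean length of maximal runs of ``target_label`` in one sequence."""
    arr = np.asarray(labels, dtype=bool)
    lengths = _run_lengths(arr, bool(target_label))
    if not lengths:
        raise ValidationError("target label absent from sequence")
    return float(np.mean(lengths))


def mean_cluster_size_multi(
    sequences: Sequence[Sequence[bool]], target_label: bool = True
) -> float:
    """Mean maximal-run length of the target label pooled across chromosomes."""
    lengths: list[int] = []
    for s in sequences:
        lengths.extend(_run_lengths(np.asarray(s, dtype=bool), bool(target_label)))
    if not lengths:
        raise ValidationError("target label absent from all sequences")
    return float(np.mean(lengths))


def activity_label_sequences(
    annotation: GenomeAnnotation, calls: pd.Series
) -> dict[str, np.ndarray]:
    """Per-chromosome ordered activity labels from per-gene calls.

    Gene order is the annotation's (chrom, start, end, gene_id) sort;
    genes missing from ``calls`` are treated as inactive.
    """
    out: dict[str, np.ndarray] = {}
    lookup = calls.astype(bool).to_dict()
    for chrom in annotation.chrom_names:
        genes = annotation.genes_on(chrom)
        if genes:
            out[chrom] = np.array([lookup.get(g.gene_id, False) for g in genes])
    return out
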