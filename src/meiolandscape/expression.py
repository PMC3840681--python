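"""Active-gene calling, signed fold changes, FDR adjustment, and X-vs-autosome contrasts.

A gene counts as actively expressed when it clears both a minimum mapped-read
floor and an FPKM threshold (strictly above).  Two conventional thresholds are
exposed: FPKM 0.1 (permissive) and FPKM 1 (the windowed-landscape default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionTable, GenomeAnnotation, ValidationError

__all__ = [
    "FPKM_THRESHOLD_PERMISSIVE",
    "FPKM_THRESHOLD_STRICT",
    "call_active",
    "call_active_table",
    "fold_change",
    "fold_change_table",
    "bh_adjust",
    "chi2_2x2",
    "chromosome_activity_contrast",
    "paired_level_test",
    "ContrastResult",
]

FPKM_THRESHOLD_PERMISSIVE = 0.1
FPKM_THRESHOLD_STRICT = 1.0
MIN_READS = 10


def call_active(
    fpkm: float,
    mapped_reads: int,
    fpkm_threshold: float = FPKM_THRESHOLD_PERMISSIVE,
    min_reads: int = MIN_READS,
) -> bool:
    """True when FPKM is strictly above the threshold and the read floor is met."""
    if fpkm < 0 or mapped_reads < 0:
        raise ValidationError("fpkm and mapped_reads must be non-negative")
    return fpkm > fpkm_threshold and mapped_reads >= min_reads


def call_active_table(
    table: ExpressionTable,
    condition: str,
    fpkm_threshold: float = FPKM_THRESHOLD_PERMISSIVE,
    min_reads: int = MIN_READS,
) -> pd.Series:
    """Per-gene activity calls for one condition.

    A gene is active when *every* sample of the condition meets the read
    floor and exceeds the FPKM threshold.  Absent cells (NaN) fail the call;
    their count is reported via the returned Series' ``attrs['n_absent']``.
    """
    cols = [s.sample_id for s in table.samples_in(condition)]
    if not cols:
        raise ValidationError(f"no samples in condition {condition!r}")
    fp = table.fpkm[cols]
    rd = table.reads[cols]
    if (fp.to_numpy() < 0).any() or (rd.fillna(0).to_numpy() < 0).any():
        raise ValidationError("negative expression values")
    ok = (fp > fpkm_threshold) & (rd >= min_reads)
    active = ok.fillna(False).all(axis=1)
    active.name = "active"
    active.attrs["n_absent"] = int(fp.isna().to_numpy().sum())
    return active


def fold_change(fpkm_a: float, fpkm_b: float) -> float:
    """Signed fold change between two FPKM values.

    Returns +a/b when a >= b, else -b/a, so the magnitude is always >= 1 and
    the sign says which condition is higher (positive: first argument).
    """
    if fpkm_a < 0 or fpkm_b < 0:
        raise ValidationError("FPKM must be non-negative")
    if fpkm_a == 0 and fpkm_b == 0:
        raise ValidationError("fold change undefined when both FPKM are zero")
    if fpkm_a == 0 or fpkm_b == 0:
        raise ValidationError(
            "fold change undefined with a zero FPKM; exclude such genes upstream"
        )
    if fpkm_a >= fpkm_b:
        return fpkm_a / fpkm_b
    return -fpkm_b / fpkm_a


def fold_change_table(
    table: ExpressionTable,
    q_values: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-gene Early-vs-Late fold changes from condition-mean FPKM.

    Genes with zero FPKM in either condition are excluded (no pseudocount)
    and counted in ``attrs['n_excluded_zero']``.  Sorted by |fold change|
    descending.
    """
    early = table.condition_mean_fpkm("Early")
    late = table.condition_mean_fpkm("Late")
    ok = (early > 0) & (late > 0)
    n_excluded = int(((early <= 0) | (late <= 0) | early.isna() | late.isna()).sum())
    early, late = early[ok.fillna(False)], late[ok.fillna(False)]
    fc = np.where(early >= late, early / late, -late / early)
    out = pd.DataFrame(
        {"fpkm_early": early, "fpkm_late": late, "fold_change": fc},
        index=early.index,
    )
    if q_values is not None:
        out["q"] = q_values.reindex(out.index)
    out = out.iloc[np.argsort(-np.abs(out["fold_change"].to_numpy()), kind="stable")]
    out.attrs["n_excluded_zero"] = n_excluded
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi2_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], no continuity
    correction by default."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("degenerate 2x2 table (empty row or column)")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


@dataclass(frozen=True)
class ContrastResult:
    proportion_x: float
    proportion_autosome: float
    chi2: float
    p: float
    n_x: int
    n_autosome: int


def chromosome_activity_contrast(
    calls: pd.Series,
    annotation: GenomeAnnotation,
    yates: bool = False,
) -> ContrastResult:
    """Compare the transcribed-gene proportion on the X against the autosomes.

    2x2 chi-square (active/inactive × X/autosome); genes on unplaced
    scaffolds are excluded.
    """
    gene_class = pd.Series(
        {g.gene_id: annotation.chrom_class(g.chrom) for g in annotation.genes}
    )
    gene_class = gene_class.reindex(calls.index)
    x_mask = gene_class == "X"
    a_mask = gene_class == "autosome"
    n_x, n_a = int(x_mask.sum()), int(a_mask.sum())
    if n_x == 0 or n_a == 0:
        raise ValidationError("need at least one gene on X and on autosomes")
    act = calls.astype(bool)
    ax, aa = int(act[x_mask].sum()), int(act[a_mask].sum())
    chi2, p = chi2_2x2(ax, n_x - ax, aa, n_a - aa, yates=yates)
    return ContrastResult(
        proportion_x=ax / n_x,
        proportion_autosome=aa / n_a,
        chi2=chi2,
        p=p,
        n_x=n_x,
        n_autosome=n_a,
    )


def paired_level_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test with normal approximation.

    Returns (Z, p), two-sided, with tie correction.  Identical vectors give
    (0, 1).  Below 10 pairs the normal approximation is unreliable and a
    warning is issued.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired vectors must have equal length")
    if a.size < 10:
        warnings.warn(
            "fewer than 10 pairs: normal approximation unreliable", stacklevel=2
        )
    diffs = a - b
    if np.all(diffs == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=False, method="approx")
    # scipy reports the smaller-tail z; re-sign it so z > 0 means the first
    # vector ranks higher (T+ exceeds its null expectation)
    nz = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(nz))
    t_signed = float(np.sum(np.sign(nz) * ranks))
    direction = np.sign(t_signed) if t_signed != 0 else 1.0
    return float(direction * abs(res.zstatistic)), float(res.pvalue)
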