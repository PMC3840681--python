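"""Parent-of-origin expression classification and allele-specific read assignment.

A gene shows a *maternal-like* parent-of-origin effect when the offspring of
the two reciprocal crosses (genetically identical, differing only in which
strain was the mother) express it at significantly different levels, and the
direction of that difference matches the direction in which the maternal
strains themselves differ.

Allele-specific assignment follows strict rules: a read is assigned to a
parental haplotype only when it matches that haplotype exactly (zero
mismatches) and does not match the other; reads over a region where either
haplotype carries an N are excluded outright; allelic ratios are only
computed for genes with at least 100 assigned reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust, paired_level_test
from .types import ValidationError

__all__ = [
    "build_reciprocal_cross_set",
    "ReciprocalCrossSet",
    "MaternalLikeResult",
    "AlleleCounts",
    "AllelicRatioResult",
    "maternal_like_genes",
    "assign_read",
    "count_alleles",
    "allelic_ratio_test",
    "MIN_ALLELE_READS",
]

MIN_ALLELE_READS = 100


@dataclass
class ReciprocalCrossSet:
    """FPKM profiles of two parental strains and their reciprocal-cross offspring.

    ``offspring_a`` is the cross whose mother is ``strain_a``; ``offspring_b``
    the cross mothered by ``strain_b``.  ``p`` (and optionally ``q``) hold the
    per-gene significance of the offspring-vs-offspring expression difference,
    supplied by an upstream differential-expression step.
    """

    strain_a: str
    strain_b: str
    parental_a: pd.Series
    parental_b: pd.Series
    offspring_a: pd.Series
    offspring_b: pd.Series
    p: pd.Series
    q: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        idx = self.parental_a.index
        for name in ("parental_b", "offspring_a", "offspring_b", "p"):
            if not getattr(self, name).index.equals(idx):
                raise ValidationError(f"{name} does not cover the same gene set")
        if self.q is None:
            self.q = pd.Series(bh_adjust(self.p.to_numpy()), index=idx)


def build_reciprocal_cross_set(
    expression,
    replicates: pd.DataFrame,
    condition: str = "Early",
    strain_a: str = "RAL-208",
    strain_b: str = "RAL-375",
    cross_a: str = "208Fx375M",
    cross_b: str = "375Fx208M",
    pseudo: float = 1e-6,
) -> ReciprocalCrossSet:
    """Assemble a :class:`ReciprocalCrossSet` from a sample table plus
    replicate-level FPKMs.

    Per-gene reciprocal-difference p-values come from a Welch t-test on
    log(FPKM + pseudo) between the replicate libraries of the two crosses —
    a deliberately simple stand-in for a full dispersion-modelling
    differential-expression step, adequate for replicate-level input.
    Genes with no variation in either cross get p = 1.
    """
    fp = expression.fpkm
    sid = lambda g: f"{g}_{condition}"
    rep = replicates[replicates["condition"] == condition]
    piv = rep.pivot_table(
        index="gene_id", columns=["genotype", "replicate"], values="fpkm"
    )
    log_a = np.log(piv[cross_a].to_numpy() + pseudo)
    log_b = np.log(piv[cross_b].to_numpy() + pseudo)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # genes with (near-)constant FPKM across libraries trip scipy's
        # precision-loss warning; they are assigned p = 1 below anyway
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    p = pd.Series(np.where(np.isfinite(p), p, 1.0), index=piv.index)
    p = p.reindex(fp.index).fillna(1.0)
    return ReciprocalCrossSet(
        strain_a=strain_a,
        strain_b=strain_b,
        parental_a=fp[sid(strain_a)],
        parental_b=fp[sid(strain_b)],
        offspring_a=fp[sid(cross_a)],
        offspring_b=fp[sid(cross_b)],
        p=p,
    )


@dataclass(frozen=True)
class MaternalLikeResult:
    maternal_like: dict[str, list[str]]  # higher-expressing maternal strain -> genes
    discordant: list[str]
    unresolved: list[str]
    n_significant: int
    q_threshold: float


def maternal_like_genes(
    crosses: ReciprocalCrossSet,
    q_threshold: float = 0.05,
    use_q: bool = True,
) -> MaternalLikeResult:
    """Classify genes with maternal-like parent-of-origin expression.

    A gene qualifies when (i) the reciprocal offspring differ significantly
    (q < threshold, or p when ``use_q`` is False) and (ii) the offspring
    difference has the same sign as the parental-strain difference, i.e.
    each cross resembles its own mother.  Maternal-like genes are split by
    which maternal strain carries the higher expression (the strain whose
    level the elevated cross resembles).  Significant genes whose offspring
    shift *against* the parental direction are reported discordant, not
    maternal-like; significant genes with no parental difference are
    unresolved.
    """
    sig_values = crosses.q if use_q else crosses.p
    significant = sig_values < q_threshold
    d_off = crosses.offspring_a - crosses.offspring_b
    d_par = crosses.parental_a - crosses.parental_b
    like_a: list[str] = []
    like_b: list[str] = []
    discordant: list[str] = []
    unresolved: list[str] = []
    for gene in crosses.parental_a.index[significant.fillna(False)]:
        po, pp = d_off[gene], d_par[gene]
        if pp == 0 or po == 0:
            unresolved.append(gene)
        elif np.sign(po) == np.sign(pp):
            (like_a if pp > 0 else like_b).append(gene)
        else:
            discordant.append(gene)
    return MaternalLikeResult(
        maternal_like={crosses.strain_a: like_a, crosses.strain_b: like_b},
        discordant=discordant,
        unresolved=unresolved,
        n_significant=int(significant.fillna(False).sum()),
        q_threshold=q_threshold,
    )


def assign_read(
    read: str, haplotype_a: str, haplotype_b: str, position: int
) -> str:
    """Assign one locus-anchored read to a parental haplotype.

    Compares the read to both parental substrings at its locus.  Returns
    ``"A"`` or ``"B"`` on an exact (zero-mismatch) match to exactly one
    parent, ``"ambiguous"`` when it matches both (no informative site) or
    neither, and ``"excluded_N"`` when either parental substring carries an
    N anywhere under the read.
    """
    end = position + len(read)
    if position < 0 or end > len(haplotype_a) or end > len(haplotype_b):
        raise ValidationError("read extends beyond a haplotype")
    sub_a = haplotype_a[position:end]
    sub_b = haplotype_b[position:end]
    if "N" in sub_a or "N" in sub_b:
        return "excluded_N"
    match_a = read == sub_a
    match_b = read == sub_b
    if match_a and not match_b:
        return "A"
    if match_b and not match_a:
        return "B"
    return "ambiguous"


@dataclass(frozen=True)
class AlleleCounts:
    gene_id: str
    reads_a: int
    reads_b: int
    excluded_n: int = 0
    ambiguous: int = 0

    @property
    def total_assigned(self) -> int:
        return self.reads_a + self.reads_b

    @property
    def ratio(self) -> Optional[float]:
        """Fraction of assigned reads from parent A; defined only at the
        100-read floor."""
        if self.total_assigned < MIN_ALLELE_READS:
            return None
        return self.reads_a / self.total_assigned


def count_alleles(
    reads: pd.DataFrame,
    haplotype_a: str,
    haplotype_b: str,
) -> pd.DataFrame:
    """Assign every read and tally per-gene allele counts.

    ``reads`` needs columns ``gene_id``, ``pos``, ``seq``.  Returns a per-gene
    frame with reads_A, reads_B, ambiguous, excluded_N, and the allelic ratio
    (NaN below the 100-read floor).  The per-read assignment is stored in
    ``attrs['assignments']``.
    """
    labels = [
        assign_read(seq, haplotype_a, haplotype_b, int(pos))
        for seq, pos in zip(reads["seq"], reads["pos"])
    ]
    lab = pd.Series(labels, index=reads.index, name="assignment")
    df = reads.assign(assignment=lab)
    grouped = df.groupby("gene_id")["assignment"]
    out = pd.DataFrame(
        {
            "reads_A": grouped.apply(lambda s: int((s == "A").sum())),
            "reads_B": grouped.apply(lambda s: int((s == "B").sum())),
            "ambiguous": grouped.apply(lambda s: int((s == "ambiguous").sum())),
            "excluded_N": grouped.apply(lambda s: int((s == "excluded_N").sum())),
        }
    )
    total = out["reads_A"] + out["reads_B"]
    out["ratio"] = np.where(
        total >= MIN_ALLELE_READS, out["reads_A"] / total.replace(0, np.nan), np.nan
    )
    out.attrs["assignments"] = lab
    return out


@dataclass(frozen=True)
class AllelicRatioResult:
    ratios: pd.Series
    n_genes: int
    excess_p: float  # two-sided sign/binomial test of ratios vs 0.5
    n_above: int
    n_below: int
    cross_shift_z: Optional[float] = None
    cross_shift_p: Optional[float] = None


def allelic_ratio_test(
    counts: pd.DataFrame,
    counts_other_cross: Optional[pd.DataFrame] = None,
    min_reads: int = MIN_ALLELE_READS,
) -> AllelicRatioResult:
    """Genome-wide allele-excess and cross-shift tests on per-gene ratios.

    Genes below the read floor are dropped.  The allele excess is a
    two-sided exact binomial (sign) test of how many gene ratios fall above
    vs below 0.5; ratios exactly 0.5 are uninformative and excluded from the
    sign test.  When the reciprocal cross' counts are supplied, the shift in
    per-gene ratios between crosses is tested with the Wilcoxon
    matched-pairs test.
    """
    total = counts["reads_A"] + counts["reads_B"]
    keep = total >= min_reads
    if not keep.any():
        raise ValidationError("no gene passes the allele-specific read floor")
    ratios = (counts.loc[keep, "reads_A"] / total[keep]).rename("ratio")
    n_above = int((ratios > 0.5).sum())
    n_below = int((ratios < 0.5).sum())
    if n_above + n_below == 0:
        excess_p = 1.0
    else:
        excess_p = float(
            stats.binomtest(n_above, n_above + n_below, 0.5).pvalue
        )
    z = p = None
    if counts_other_cross is not None:
        total2 = counts_other_cross["reads_A"] + counts_other_cross["reads_B"]
        keep2 = total2 >= min_reads
        common = ratios.index.intersection(counts_other_cross.index[keep2])
        if len(common) >= 2:
            other = (
                counts_other_cross.loc[common, "reads_A"] / total2[common]
            )
            z, p = paired_level_test(ratios[common].to_numpy(), other.to_numpy())
    return AllelicRatioResult(
        ratios=ratios,
        n_genes=int(keep.sum()),
        excess_p=excess_p,
        n_above=n_above,
        n_below=n_below,
        cross_shift_z=z,
        cross_shift_p=p,
    )
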