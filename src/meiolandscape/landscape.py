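"""Windowed transcription landscapes and their association with recombination.

Each chromosome is tiled with adjacent fixed-size windows (100 kb by default)
and three per-window transcription metrics are computed:

* ``n_transcribed`` — transcribed genes whose midpoint falls in the window;
* ``kb_transcribed`` — kilobases covered by the union of transcribed genes'
  genomic footprints, clipped to the window (overlaps counted once);
* ``ota`` — overall transcriptional activity, log10 of the summed
  FPKM × transcript length over transcribed genes assigned to the window;
  undefined (NaN) when the window holds no transcribed gene.

A gene contributes its midpoint window only for counting and OTA (no
double-counting of FPKM mass), while kb_transcribed clips the genomic
footprint to every window it touches.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import GenomeAnnotation, RecombinationMap, ValidationError

__all__ = [
    "bin_genome",
    "window_metrics",
    "align_windows",
    "correlate_with_recombination",
    "multiple_regression",
    "zero_vs_nonzero_transcription",
]

WINDOW_SIZE = 100_000
METRIC_COLUMNS = ["n_transcribed", "kb_transcribed", "ota"]


def bin_genome(
    annotation: GenomeAnnotation, window_size: int = WINDOW_SIZE
) -> pd.DataFrame:
    """Tile every chromosome with adjacent left-closed windows.

    The final partial window is kept and flagged ``partial`` so downstream
    correlation steps can drop it (its per-Mb normalization differs).
    """
    if window_size <= 0:
        raise ValidationError("window_size must be > 0")
    rows = []
    for c in annotation.chromosomes:
        starts = np.arange(0, c.length, window_size)
        for s in starts:
            e = min(s + window_size, c.length)
            rows.append((c.name, int(s), int(e), e - s < window_size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def _merged_intervals(genes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted (start, end) intervals into a disjoint union."""
    if genes.empty:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.asarray(m_starts), np.asarray(m_ends)


def _union_overlap(
    m_starts: np.ndarray, m_ends: np.ndarray, wstart: int, wend: int
) -> int:
    i = int(np.searchsorted(m_ends, wstart, side="right"))
    j = int(np.searchsorted(m_starts, wend, side="left"))
    if i >= j:
        return 0
    return int(
        np.sum(np.minimum(m_ends[i:j], wend) - np.maximum(m_starts[i:j], wstart))
    )


def window_metrics(
    annotation: GenomeAnnotation,
    expression_calls: pd.DataFrame,
    windows: pd.DataFrame,
    fpkm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-window transcription metrics.

    ``expression_calls`` is a per-gene frame with columns ``active`` (bool,
    computed at ``fpkm_threshold``) and ``fpkm`` (the level used inside OTA).
    Returns the ``windows`` frame with n_transcribed, kb_transcribed and ota
    columns appended.
    """
    genes = annotation.gene_frame()
    unknown = set(genes["chrom"]) - set(annotation.chrom_names)
    if unknown:
        raise ValidationError(f"genes on unknown chromosomes: {sorted(unknown)}")
    calls = expression_calls.reindex(genes.index)
    active = calls["active"].fillna(False).to_numpy(dtype=bool)
    fpkm = calls["fpkm"].fillna(0.0).to_numpy(dtype=float)
    tlen = genes["transcript_length"].to_numpy(dtype=float)
    weight = fpkm * tlen

    out = windows.copy()
    n_t = np.zeros(len(out), dtype=int)
    kb_t = np.zeros(len(out), dtype=float)
    ota_sum = np.zeros(len(out), dtype=float)

    for chrom, wgrp in out.groupby("chrom", sort=False):
        wstarts = wgrp["start"].to_numpy()
        wends = wgrp["end"].to_numpy()
        widx = wgrp.index.to_numpy()
        gmask = (genes["chrom"] == chrom).to_numpy() & active
        gsub = genes[gmask]
        if gsub.empty:
            continue
        mid = ((gsub["start"] + gsub["end"]) // 2).to_numpy()
        w_of_gene = np.searchsorted(wstarts, mid, side="right") - 1
        valid = (w_of_gene >= 0) & (mid < wends[np.clip(w_of_gene, 0, None)])
        np.add.at(n_t, widx[w_of_gene[valid]], 1)
        np.add.at(ota_sum, widx[w_of_gene[valid]], weight[gmask][valid])
        m_starts, m_ends = _merged_intervals(gsub)
        for k, wi in enumerate(widx):
            kb_t[wi] = _union_overlap(m_starts, m_ends, wstarts[k], wends[k]) / 1000.0

    out["n_transcribed"] = n_t
    out["kb_transcribed"] = kb_t
    ota = np.full(len(out), np.nan)
    defined = ota_sum > 0
    ota[defined] = np.log10(ota_sum[defined])
    out["ota"] = ota
    return out


def align_windows(
    metrics: pd.DataFrame,
    recomb_map: RecombinationMap,
    include_partial: bool = False,
) -> pd.DataFrame:
    """Join window metrics with recombination rates on exact (chrom, start, end).

    Windows without a rate estimate are dropped and counted in
    ``attrs['n_dropped_no_rate']``; partial terminal windows are dropped by
    default.
    """
    m = metrics if include_partial else metrics[~metrics["partial"]]
    joined = m.merge(
        recomb_map.windows, on=["chrom", "start", "end"], how="left", validate="1:1"
    )
    n_missing = int(joined["rate"].isna().sum())
    joined = joined[joined["rate"].notna()].reset_index(drop=True)
    joined.attrs["n_dropped_no_rate"] = n_missing
    return joined


def correlate_with_recombination(
    metrics: pd.DataFrame,
    recomb_map: RecombinationMap,
    method: str = "spearman",
    include_partial: bool = False,
) -> pd.DataFrame:
    """Rank-correlate each window metric with the recombination rate.

    Windows with an undefined metric (OTA in empty windows) are dropped for
    that metric only.  Returns one row per metric: rho, p, n.
    """
    joined = align_windows(metrics, recomb_map, include_partial=include_partial)
    rows = []
    for col in METRIC_COLUMNS:
        sub = joined[[col, "rate"]].dropna()
        if len(sub) < 3:
            raise ValidationError(f"fewer than 3 aligned windows for {col}")
        if method == "spearman":
            rho, p = stats.spearmanr(sub[col], sub["rate"])
        elif method == "pearson":
            rho, p = stats.pearsonr(sub[col], sub["rate"])
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows.append((col, float(rho), float(p), len(sub)))
    return pd.DataFrame(rows, columns=["metric", "rho", "p", "n"])


def multiple_regression(
    metrics: pd.DataFrame,
    recomb_map: RecombinationMap,
    include_partial: bool = False,
    rank_transform: bool = False,
    min_windows: int = 10,
    ota_impute_offset: float = 1.0,
) -> pd.DataFrame:
    """OLS of recombination rate on the three window metrics with intercept.

    Windows with undefined OTA get the minimum observed OTA minus
    ``ota_impute_offset`` (the count of imputed windows is reported in
    ``attrs['n_ota_imputed']``).  With ``rank_transform`` all variables are
    converted to average ranks first.  Returns per-predictor coefficient,
    two-sided t-test p, and n.
    """
    joined = align_windows(metrics, recomb_map, include_partial=include_partial)
    if len(joined) < min_windows:
        raise ValidationError(
            f"need at least {min_windows} windows for regression, got {len(joined)}"
        )
    X = joined[METRIC_COLUMNS].astype(float).copy()
    n_imputed = int(X["ota"].isna().sum())
    if n_imputed:
        if X["ota"].notna().any():
            X.loc[X["ota"].isna(), "ota"] = X["ota"].min() - ota_impute_offset
        else:
            raise ValidationError("OTA undefined in every window (constant predictor)")
    y = joined["rate"].astype(float)
    for col in METRIC_COLUMNS:
        if np.isclose(X[col].std(ddof=0), 0.0):
            raise ValidationError(f"constant predictor: {col}")
    if rank_transform:
        X = X.rank(method="average")
        y = y.rank(method="average")
    names = ["intercept"] + METRIC_COLUMNS
    if np.isclose(y.std(ddof=0), 0.0):
        # constant response carries no signal: zero slopes, p = 1
        params = np.array([float(y.mean()), 0.0, 0.0, 0.0])
        pvals = np.array([0.0, 1.0, 1.0, 1.0])
    else:
        model = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        params = model.params
        # a perfect (zero-residual) fit has no sampling variance; report p = 1
        pvals = np.where(np.isnan(model.pvalues), 1.0, model.pvalues)
    out = pd.DataFrame(
        {
            "predictor": names,
            "coefficient": params,
            "p": pvals,
            "n": len(joined),
        }
    )
    out.attrs["n_ota_imputed"] = n_imputed
    return out


def zero_vs_nonzero_transcription(
    metrics: pd.DataFrame,
    recomb_map: RecombinationMap,
    include_partial: bool = False,
) -> tuple[float, float]:
    """Mann–Whitney U comparing rates of windows with no transcribed gene
    against windows with at least one.  Returns (U, p), two-sided."""
    joined = align_windows(metrics, recomb_map, include_partial=include_partial)
    zero = joined.loc[joined["n_transcribed"] == 0, "rate"]
    nonzero = joined.loc[joined["n_transcribed"] >= 1, "rate"]
    if zero.empty or nonzero.empty:
        raise ValidationError("both window groups (zero / nonzero) must be nonempty")
    u, p = stats.mannwhitneyu(zero, nonzero, alternative="two-sided")
    return float(u), float(p)
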