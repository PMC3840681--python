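"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the salient structure of an early-meiosis ovarian
RNA-seq study on a scaled-down fly-like genome: physically clustered
active genes (two-state Markov chain along gene order), an excess of
transcribed genes on the X, lognormal FPKM among active genes, a
recombination landscape with a bell-shaped chromosomal trend plus a
configurable linear dependence on window transcription, DSB events placed
category-first with configurable enrichment weights, reciprocal-cross
expression with planted maternal-like effects, and SNP-bearing parental
haplotypes with error-free reads of known allelic origin.

Every sampler draws from an explicit generator stream derived from the one
config seed; a fixed seed reproduces every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import dsb as dsb_mod
from .expression import call_active_table
from .landscape import bin_genome, window_metrics
from .types import (
    Chromosome,
    DSBEventSet,
    ExpressionTable,
    Gene,
    GenomeAnnotation,
    RecombinationMap,
    SampleMeta,
    ValidationError,
)
from .io import infer_chrom_class

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_genome",
    "generate_expression",
    "generate_recombination_map",
    "generate_dsbs",
    "generate_haplotypes_and_reads",
    "generate_novel_candidates",
]

GENOTYPES = ("RAL-208", "RAL-375", "375Fx208M", "208Fx375M")
MATERNAL_OF = {"375Fx208M": "RAL-375", "208Fx375M": "RAL-208"}
CONDITIONS = ("Early", "Late")

# stream ids for the per-stage generator states
_STREAM_GENOME = 1
_STREAM_EXPRESSION = 2
_STREAM_RECOMB = 3
_STREAM_DSB = 4
_STREAM_READS = 5
_STREAM_NOVEL = 6


def _default_chrom_lengths() -> dict[str, int]:
    return {"chr2L": 5_000_000, "chr2R": 5_000_000, "chrX": 4_000_000}


def _default_dsb_weights() -> dict[str, float]:
    return {name: 1.0 for name in dsb_mod.CATEGORIES}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults defining its conditions.

    Probabilities must lie in [0, 1] and weights be non-negative; a fixed
    ``seed`` makes every generator bit-reproducible.
    """

    seed: int = 0
    # genome
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    n_genes: int = 1500
    gene_length_log_mean: float = 7.9  # ln bp; median footprint ~2.7 kb
    gene_length_log_sigma: float = 0.6
    exonic_fraction_range: tuple[float, float] = (0.5, 0.95)
    # expression
    clustering_strength: float = 0.6  # P(consecutive genes share activity state)
    p_active_x: float = 0.62
    p_active_autosome: float = 0.55
    fpkm_log_mean: float = 2.0  # natural-log lognormal parameters for active genes
    fpkm_log_sigma: float = 1.5
    condition_sigma: float = 0.4  # per-gene Early-vs-Late log effect SD
    strain_sigma: float = 0.3  # per-gene strain log effect SD
    replicate_sigma: float = 0.15  # library-to-library log noise SD
    n_replicates: int = 3  # libraries per genotype x condition
    mapped_millions: float = 5.0  # scales FPKM x kb into mapped reads
    maternal_effect_fraction: float = 0.1
    maternal_effect_size: float = 0.9  # offspring weight toward the maternal parent
    maternal_parental_diff: float = 1.5  # planted |log FPKM| parental gap
    # recombination map
    window_size: int = 100_000
    recomb_base_rate: float = 2.0  # cM/Mb
    beta_genes: float = 0.15
    beta_kb: float = 0.02
    beta_ota: float = 0.0
    recomb_trend_amplitude: float = 1.5
    recomb_noise_sd: float = 0.8
    # DSBs
    n_dsbs: int = 5610
    dsb_max_width: int = 500
    dsb_category_weights: dict[str, float] = field(default_factory=_default_dsb_weights)
    # haplotypes and reads
    hap_length: int = 60_000
    n_hap_genes: int = 20
    snp_density: float = 0.005  # SNPs per bp between the parental strains
    n_rate: float = 0.001  # probability a parent-B base is N
    read_length: int = 120
    n_reads: int = 10_000
    allele_ratio: float = 0.5  # fraction of reads drawn from parent A

    def __post_init__(self) -> None:
        for name in (
            "clustering_strength",
            "p_active_x",
            "p_active_autosome",
            "maternal_effect_fraction",
            "maternal_effect_size",
            "snp_density",
            "n_rate",
            "allele_ratio",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if any(w < 0 for w in self.dsb_category_weights.values()):
            raise ValidationError("dsb_category_weights must be non-negative")
        unknown = set(self.dsb_category_weights) - set(dsb_mod.CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown DSB categories: {sorted(unknown)}")
        if self.n_genes < 0 or self.n_dsbs < 0 or self.n_reads < 0:
            raise ValidationError("counts must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator stream for one stage."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the synthetic data.

    ``genes``: per-gene activity state, maternal-effect flag and the strain
    whose level the effect favors.  ``replicates``: long table of per-library
    FPKM draws underlying each merged sample.
    """

    genes: pd.DataFrame
    replicates: pd.DataFrame


# ---------------------------------------------------------------------------
# genome

def generate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes along the configured chromosomes.

    Gene footprints are lognormal; genes are allotted to chromosomes in
    proportion to length and separated by uniformly broken intergenic gaps.
    One chromosome (any whose name implies it) is classed X.
    """
    rng = config.rng(_STREAM_GENOME)
    chrom_names = sorted(config.chrom_lengths)
    total_len = sum(config.chrom_lengths.values())
    chroms = [
        Chromosome(name, config.chrom_lengths[name], infer_chrom_class(name))
        for name in chrom_names
    ]
    genes: list[Gene] = []
    remaining = config.n_genes
    counter = 0
    for i, name in enumerate(chrom_names):
        length = config.chrom_lengths[name]
        if i == len(chrom_names) - 1:
            n_c = remaining
        else:
            n_c = int(round(config.n_genes * length / total_len))
            n_c = min(n_c, remaining)
        remaining -= n_c
        if n_c == 0:
            continue
        footprints = np.round(
            rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sigma, n_c)
        ).astype(np.int64)
        footprints = np.maximum(footprints, 200)
        if footprints.sum() >= length:
            raise ValidationError(
                f"requested gene footprint exceeds {name} length "
                f"({footprints.sum()} >= {length})"
            )
        free = length - int(footprints.sum())
        gap_cum = np.floor(np.sort(rng.random(n_c)) * free).astype(np.int64)
        starts = gap_cum + np.concatenate([[0], np.cumsum(footprints[:-1])])
        lo, hi = config.exonic_fraction_range
        exonic = rng.uniform(lo, hi, n_c)
        strands = rng.choice(["+", "-"], n_c)
        for j in range(n_c):
            counter += 1
            genes.append(
                Gene(
                    gene_id=f"gene_{counter:05d}",
                    chrom=name,
                    start=int(starts[j]),
                    end=int(starts[j] + footprints[j]),
                    strand=str(strands[j]),
                    transcript_length=max(50, int(round(footprints[j] * exonic[j]))),
                )
            )
    return GenomeAnnotation(chromosomes=chroms, genes=genes)


# ---------------------------------------------------------------------------
# expression

def generate_expression(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[ExpressionTable, SyntheticTruth]:
    """Eight-sample expression table (4 genotypes × Early/Late) with truth.

    Activity states run as a Markov chain along gene order (persistence =
    ``clustering_strength``, marginal activity probability higher on the X).
    Active genes get lognormal FPKM with per-gene condition and strain
    effects; a ``maternal_effect_fraction`` of active genes get a planted
    parental gap and offspring levels pulled toward the maternal strain by
    ``maternal_effect_size``.  Sample FPKM is the mean over
    ``n_replicates`` simulated libraries.
    """
    if not annotation.genes:
        raise ValidationError("annotation has no genes")
    rng = config.rng(_STREAM_EXPRESSION)
    genes = annotation.genes
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]

    # Markov activity states along each chromosome
    active = np.zeros(n, dtype=bool)
    pos = 0
    for chrom in annotation.chrom_names:
        chrom_genes = annotation.genes_on(chrom)
        m = len(chrom_genes)
        if m == 0:
            continue
        p = (
            config.p_active_x
            if annotation.chrom_class(chrom) == "X"
            else config.p_active_autosome
        )
        states = np.zeros(m, dtype=bool)
        states[0] = rng.random() < p
        keep = rng.random(m) < config.clustering_strength
        fresh = rng.random(m) < p
        for i in range(1, m):
            states[i] = states[i - 1] if keep[i] else fresh[i]
        active[pos : pos + m] = states
        pos += m

    base = rng.normal(config.fpkm_log_mean, config.fpkm_log_sigma, n)
    cond_eff = rng.normal(0.0, config.condition_sigma, n)
    strain_eff = rng.normal(0.0, config.strain_sigma, n)

    maternal_flag = active & (rng.random(n) < config.maternal_effect_fraction)
    maternal_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    strain_eff = np.where(
        maternal_flag, maternal_sign * config.maternal_parental_diff, strain_eff
    )
    # log-level of strain RAL-208 is base + eff/2, RAL-375 is base - eff/2
    w = config.maternal_effect_size

    def log_level(genotype: str, condition: str) -> np.ndarray:
        mu = base + np.where(np.array(condition) == "Early", 1, -1) * cond_eff / 2.0
        if genotype == "RAL-208":
            return mu + strain_eff / 2.0
        if genotype == "RAL-375":
            return mu - strain_eff / 2.0
        # reciprocal offspring: midparent, pulled toward the maternal parent
        maternal = MATERNAL_OF[genotype]
        direction = 1.0 if maternal == "RAL-208" else -1.0
        shift = np.where(maternal_flag, w * direction * strain_eff / 2.0, 0.0)
        return mu + shift

    tlen_kb = np.array([g.transcript_length for g in genes]) / 1000.0
    samples: list[SampleMeta] = []
    fpkm_cols: dict[str, np.ndarray] = {}
    reads_cols: dict[str, np.ndarray] = {}
    rep_rows = []
    for genotype in GENOTYPES:
        for condition in CONDITIONS:
            sid = f"{genotype}_{condition}"
            mu = log_level(genotype, condition)
            reps = np.exp(
                mu[None, :]
                + rng.normal(0.0, config.replicate_sigma, (config.n_replicates, n))
            )
            reps[:, ~active] = 0.0
            fpkm = reps.mean(axis=0)
            reads = rng.poisson(fpkm * tlen_kb * config.mapped_millions)
            fpkm_cols[sid] = fpkm
            reads_cols[sid] = reads
            mapped = int(reads.sum())
            gross = int(round(mapped / rng.uniform(0.72, 0.86))) if mapped else 0
            samples.append(
                SampleMeta(
                    sample_id=sid,
                    condition=condition,
                    genotype=genotype,
                    maternal_strain=MATERNAL_OF.get(genotype),
                    gross_reads=gross,
                    mapped_reads=mapped,
                )
            )
            for r in range(config.n_replicates):
                rep_rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_ids,
                            "genotype": genotype,
                            "condition": condition,
                            "replicate": r + 1,
                            "fpkm": reps[r],
                        }
                    )
                )

    index = pd.Index(gene_ids, name="gene_id")
    table = ExpressionTable(
        samples=samples,
        fpkm=pd.DataFrame(fpkm_cols, index=index),
        reads=pd.DataFrame(reads_cols, index=index),
    )
    truth_genes = pd.DataFrame(
        {
            "active": active,
            "maternal_flag": maternal_flag,
            "maternal_high_strain": np.where(
                maternal_flag,
                np.where(strain_eff > 0, "RAL-208", "RAL-375"),
                ".",
            ),
        },
        index=index,
    )
    truth = SyntheticTruth(
        genes=truth_genes, replicates=pd.concat(rep_rows, ignore_index=True)
    )
    return table, truth


# ---------------------------------------------------------------------------
# recombination map

def generate_recombination_map(
    annotation: GenomeAnnotation,
    expression: ExpressionTable,
    config: SimulationConfig,
) -> RecombinationMap:
    """Windowed recombination rates with a planted dependence on transcription.

    rate = max(0, base + beta_genes·n_transcribed + beta_kb·kb_transcribed +
    beta_ota·OTA + bell-shaped chromosomal trend + Gaussian noise), per
    adjacent window; OTA enters as 0 where undefined.
    """
    rng = config.rng(_STREAM_RECOMB)
    windows = bin_genome(annotation, config.window_size)
    calls = pd.DataFrame(
        {
            "active": call_active_table(expression, "Early", fpkm_threshold=1.0),
            "fpkm": expression.condition_mean_fpkm("Early"),
        }
    )
    metrics = window_metrics(annotation, calls, windows, fpkm_threshold=1.0)
    centers = (metrics["start"] + metrics["end"]) / 2.0
    lengths = metrics["chrom"].map(
        {c.name: c.length for c in annotation.chromosomes}
    )
    trend = config.recomb_trend_amplitude * np.sin(np.pi * centers / lengths)
    ota = metrics["ota"].fillna(0.0)
    rate = (
        config.recomb_base_rate
        + config.beta_genes * metrics["n_transcribed"]
        + config.beta_kb * metrics["kb_transcribed"]
        + config.beta_ota * ota
        + trend
        + rng.normal(0.0, config.recomb_noise_sd, len(metrics))
    )
    out = metrics[["chrom", "start", "end"]].copy()
    out["rate"] = np.maximum(rate.to_numpy(), 0.0)
    return RecombinationMap(windows=out)


# ---------------------------------------------------------------------------
# DSB events

def generate_dsbs(
    annotation: GenomeAnnotation,
    expression: ExpressionTable,
    config: SimulationConfig,
) -> DSBEventSet:
    """DSB events drawn category-first with configurable enrichment weights.

    A category is chosen with probability proportional to weight × footprint,
    then a midpoint uniformly within that category's footprint; the event
    interval (≤ ``dsb_max_width`` bp) is centered on the midpoint and clipped
    to the chromosome.  True categories ride along in a ``category`` column.
    """
    rng = config.rng(_STREAM_DSB)
    partition = dsb_mod.build_partition(
        annotation, expression.condition_mean_fpkm("Early")
    )
    # per-category segment inventory: (chrom, start, length) rows
    seg_rows: dict[str, list[tuple[str, int, int]]] = {
        name: [] for name in dsb_mod.CATEGORIES
    }
    for chrom, (bounds, cats) in partition.segments.items():
        for s, e, c in zip(bounds[:-1], bounds[1:], cats):
            seg_rows[dsb_mod.CATEGORIES[int(c)]].append((chrom, int(s), int(e - s)))

    names, probs = [], []
    for name in dsb_mod.CATEGORIES:
        footprint = sum(length for _, _, length in seg_rows[name])
        weight = config.dsb_category_weights.get(name, 1.0)
        mass = weight * footprint
        if mass > 0:
            names.append(name)
            probs.append(mass)
    if not names:
        raise ValidationError("every DSB category has zero placement mass")
    probs_arr = np.asarray(probs, dtype=float)
    probs_arr /= probs_arr.sum()

    chosen = rng.choice(len(names), size=config.n_dsbs, p=probs_arr)
    rows = []
    for cat_idx, name in enumerate(names):
        m = int((chosen == cat_idx).sum())
        if m == 0:
            continue
        segs = seg_rows[name]
        chroms = np.array([c for c, _, _ in segs])
        starts_arr = np.array([s for _, s, _ in segs], dtype=np.int64)
        lens_arr = np.array([length for _, _, length in segs], dtype=np.int64)
        cum = np.cumsum(lens_arr)
        offsets = rng.integers(0, cum[-1], m)
        seg_idx = np.searchsorted(cum, offsets, side="right")
        within = offsets - (cum[seg_idx] - lens_arr[seg_idx])
        mids = starts_arr[seg_idx] + within
        widths = rng.integers(50, config.dsb_max_width + 1, m)
        for chrom, mid, width in zip(chroms[seg_idx], mids, widths):
            chrom_len = partition.chrom_lengths[str(chrom)]
            start = max(0, int(mid) - int(width) // 2)
            end = min(chrom_len, start + int(width))
            start = max(0, min(start, end - 1))
            rows.append((str(chrom), start, end, name))
    events = pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])
    return DSBEventSet(events=events, max_width=config.dsb_max_width)


# ---------------------------------------------------------------------------
# haplotypes and reads

def generate_haplotypes_and_reads(
    config: SimulationConfig,
) -> tuple[str, str, pd.DataFrame, pd.DataFrame]:
    """Two parental haplotypes plus error-free reads of known origin.

    Parent B equals parent A with substitutions at ``snp_density`` and Ns at
    ``n_rate``.  Reads are exact substrings of their parent of origin
    (fraction ``allele_ratio`` from A), uniform along the haplotype, and are
    labelled with their true origin and the gene segment they start in.

    Returns (haplotype A, haplotype B, reads frame, genes frame).
    """
    rng = config.rng(_STREAM_READS)
    L = config.hap_length
    if config.read_length > L:
        raise ValidationError("read_length exceeds haplotype length")
    alphabet = np.array(list("ACGT"))
    idx_a = rng.integers(0, 4, L)
    snp = rng.random(L) < config.snp_density
    shift = rng.integers(1, 4, L)
    idx_b = np.where(snp, (idx_a + shift) % 4, idx_a)
    bases_a = alphabet[idx_a]
    bases_b = alphabet[idx_b].copy()
    n_mask = rng.random(L) < config.n_rate
    bases_b[n_mask] = "N"
    hap_a = "".join(bases_a)
    hap_b = "".join(bases_b)

    seg = max(1, L // max(1, config.n_hap_genes))
    gene_starts = np.arange(0, L, seg)[: config.n_hap_genes]
    gene_ends = np.append(gene_starts[1:], L)
    genes = pd.DataFrame(
        {
            "gene_id": [f"hgene_{i:03d}" for i in range(len(gene_starts))],
            "start": gene_starts,
            "end": gene_ends,
        }
    )

    from_a = rng.random(config.n_reads) < config.allele_ratio
    positions = rng.integers(0, L - config.read_length + 1, config.n_reads)
    seqs = [
        (hap_a if a else hap_b)[p : p + config.read_length]
        for a, p in zip(from_a, positions)
    ]
    gene_idx = np.clip(
        np.searchsorted(gene_starts, positions, side="right") - 1, 0, len(gene_starts) - 1
    )
    reads = pd.DataFrame(
        {
            "read_id": [f"read_{i:06d}" for i in range(config.n_reads)],
            "gene_id": genes["gene_id"].to_numpy()[gene_idx],
            "pos": positions,
            "seq": seqs,
            "true_origin": np.where(from_a, "A", "B"),
        }
    )
    return hap_a, hap_b, reads, genes


# ---------------------------------------------------------------------------
# novel-transcript candidates

def generate_novel_candidates(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    n_candidates: int = 200,
    n_samples: int = 8,
):
    """Unannotated-transcript candidates with planted filter outcomes.

    Each candidate is given attributes that independently pass or fail the
    three cascade stages (detection breadth, peak FPKM, length/repeats/
    junction support) so downstream per-stage survivor counts are known by
    construction.  Returns a list of :class:`~meiolandscape.novel.NovelCandidate`.
    """
    from .novel import NovelCandidate

    rng = config.rng(_STREAM_NOVEL)
    chroms = [c.name for c in annotation.chromosomes]
    lengths = {c.name: c.length for c in annotation.chromosomes}
    candidates = []
    for i in range(n_candidates):
        chrom = str(rng.choice(chroms))
        length = int(rng.integers(80, 2000))
        start = int(rng.integers(0, max(1, lengths[chrom] - length)))
        n_detected = int(rng.integers(0, n_samples + 1))
        peak = float(np.round(rng.lognormal(0.0, 1.2), 3))
        fpkm = np.zeros(n_samples)
        if n_detected:
            cols = rng.choice(n_samples, n_detected, replace=False)
            fpkm[cols] = np.round(rng.uniform(0.05, 1.0, n_detected), 3)
            fpkm[cols[0]] = peak
        candidates.append(
            NovelCandidate(
                id=f"novel_{i:04d}",
                chrom=chrom,
                start=start,
                end=start + length,
                fpkm=tuple(fpkm),
                repetitive_fraction=float(np.round(rng.uniform(0.0, 1.0), 3)),
                splice_junction_support=bool(rng.random() < 0.7),
            )
        )
    return candidates
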