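"""Stage orchestration: run the analyses end to end over files on disk.

Each stage reads the standard-format inputs written by the simulate stage
(or supplied by the user), computes its tables through the library modules,
and writes TSV results.  A run manifest (package version, seed, config hash,
per-stage row counts) makes reruns auditable; under a fixed seed every
output table is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import clustering as clustering_mod
from . import dsb as dsb_mod
from . import expression as expr_mod
from . import io as io_mod
from . import landscape as landscape_mod
from . import novel as novel_mod
from . import parent_of_origin as poe_mod
from . import simulate as sim_mod
from .types import ValidationError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "expression", "clustering", "landscape", "dsb", "poe", "novel")

__all__ = ["PipelineConfig", "run", "STAGES"]


@dataclass
class PipelineConfig:
    """Declarative run configuration; thresholds default to the conventional
    values (FPKM 0.1/1 activity, 0.001 silent, 10-read floor, q < 0.05,
    100 allele-specific reads, 100-kb windows, 10,000 null replicates)."""

    outdir: Path = Path("pipeline_out")
    seed: int = 0
    fpkm_active: float = 0.1
    fpkm_strict: float = 1.0
    silent_threshold: float = 0.001
    min_reads: int = 10
    q_threshold: float = 0.05
    min_allele_reads: int = 100
    window_size: int = 100_000
    n_replicates: int = 10_000
    simulation: sim_mod.SimulationConfig = field(
        default_factory=sim_mod.SimulationConfig
    )

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in (
            "fpkm_active",
            "fpkm_strict",
            "silent_threshold",
            "q_threshold",
            "window_size",
            "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.min_reads < 0 or self.min_allele_reads < 0:
            raise ValidationError("read floors must be non-negative")
        # keep the simulation on the pipeline's seed and window size
        self.simulation = dataclasses.replace(
            self.simulation, seed=self.seed, window_size=self.window_size
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.pop("simulation", {}) or {}
        if "chrom_lengths" in sim_kwargs:
            sim_kwargs["chrom_lengths"] = {
                str(k): int(v) for k, v in sim_kwargs["chrom_lengths"].items()
            }
        if "exonic_fraction_range" in sim_kwargs:
            sim_kwargs["exonic_fraction_range"] = tuple(
                sim_kwargs["exonic_fraction_range"]
            )
        sim = sim_mod.SimulationConfig(**sim_kwargs)
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        blob = json.dumps(encode(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _paths(cfg: PipelineConfig) -> dict[str, Path]:
    d = cfg.outdir
    return {
        "annotation": d / "annotation.gff3",
        "expression": d / "expression.tsv",
        "recomb_map": d / "recombination_map.tsv",
        "dsbs": d / "dsb_events.bed",
        "hap_a": d / "haplotype_A.fasta",
        "hap_b": d / "haplotype_B.fasta",
        "reads": d / "reads.tsv",
        "hap_genes": d / "haplotype_genes.tsv",
        "truth_genes": d / "truth_genes.tsv",
        "truth_replicates": d / "truth_replicates.tsv",
        "novel_candidates": d / "novel_candidates.tsv",
    }


def _load_inputs(cfg: PipelineConfig):
    p = _paths(cfg)
    for key in ("annotation", "expression"):
        if not p[key].exists():
            raise FileNotFoundError(
                f"missing input {p[key]}; run the simulate stage first"
            )
    annotation = io_mod.read_annotation(p["annotation"], format="gff3")
    expression = io_mod.read_expression(p["expression"])
    return annotation, expression


def _calls_frame(expression, annotation, threshold, min_reads, condition="Early"):
    active = expr_mod.call_active_table(
        expression, condition, fpkm_threshold=threshold, min_reads=min_reads
    )
    return pd.DataFrame(
        {"active": active, "fpkm": expression.condition_mean_fpkm(condition)}
    )


def _stage_simulate(cfg: PipelineConfig) -> dict[str, int]:
    p = _paths(cfg)
    sim = cfg.simulation
    annotation = sim_mod.generate_genome(sim)
    expression, truth = sim_mod.generate_expression(annotation, sim)
    rmap = sim_mod.generate_recombination_map(annotation, expression, sim)
    events = sim_mod.generate_dsbs(annotation, expression, sim)
    hap_a, hap_b, reads, hap_genes = sim_mod.generate_haplotypes_and_reads(sim)
    candidates = sim_mod.generate_novel_candidates(annotation, sim)

    io_mod.write_annotation_gff3(annotation, p["annotation"])
    io_mod.write_expression(expression, p["expression"])
    io_mod.write_recombination_map(rmap, p["recomb_map"])
    io_mod.write_dsb_bed(events, p["dsbs"])
    io_mod.write_fasta({"RAL-208": hap_a, "RAL-375": hap_b}, p["hap_a"].parent / "haplotypes.fasta")
    io_mod.write_fasta({"RAL-208": hap_a}, p["hap_a"])
    io_mod.write_fasta({"RAL-375": hap_b}, p["hap_b"])
    io_mod.write_table(reads, p["reads"])
    io_mod.write_table(hap_genes, p["hap_genes"])
    io_mod.write_table(truth.genes.reset_index(), p["truth_genes"])
    io_mod.write_table(truth.replicates, p["truth_replicates"])
    cand_rows = pd.DataFrame(
        [
            {
                "id": c.id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "repetitive_fraction": c.repetitive_fraction,
                "splice_junction_support": c.splice_junction_support,
                **{f"fpkm_s{i + 1}": v for i, v in enumerate(c.fpkm)},
            }
            for c in candidates
        ]
    )
    io_mod.write_table(cand_rows, p["novel_candidates"])
    return {
        "genes": len(annotation.genes),
        "samples": len(expression.samples),
        "windows": len(rmap),
        "dsbs": len(events),
        "reads": len(reads),
        "novel_candidates": len(cand_rows),
    }


def _stage_expression(cfg: PipelineConfig) -> dict[str, int]:
    annotation, expression = _load_inputs(cfg)
    d = cfg.outdir

    rows = []
    for s in expression.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "gross_reads": s.gross_reads,
                "mapped_reads": s.mapped_reads,
                "percent_mapped": round(
                    io_mod.percent_mapped(s.gross_reads, s.mapped_reads), 2
                )
                if s.gross_reads
                else float("nan"),
            }
        )
    io_mod.write_table(pd.DataFrame(rows), d / "mapping_summary.tsv")

    fc = expr_mod.fold_change_table(expression)
    io_mod.write_table(
        fc.reset_index().rename(columns={"index": "gene_id"}), d / "fold_changes.tsv"
    )

    contrast_rows = []
    for thr in (cfg.fpkm_active, cfg.fpkm_strict):
        for condition in ("Early", "Late"):
            calls = expr_mod.call_active_table(
                expression, condition, fpkm_threshold=thr, min_reads=cfg.min_reads
            )
            res = expr_mod.chromosome_activity_contrast(calls, annotation)
            contrast_rows.append(
                {
                    "condition": condition,
                    "fpkm_threshold": thr,
                    "proportion_X": res.proportion_x,
                    "proportion_autosome": res.proportion_autosome,
                    "chi2": res.chi2,
                    "p": res.p,
                }
            )
    io_mod.write_table(pd.DataFrame(contrast_rows), d / "x_vs_autosome.tsv")
    return {"fold_change_genes": len(fc), "contrasts": len(contrast_rows)}


def _stage_clustering(cfg: PipelineConfig) -> dict[str, int]:
    annotation, expression = _load_inputs(cfg)
    rows = []
    for thr in (cfg.fpkm_strict, cfg.fpkm_active):
        calls = expr_mod.call_active_table(
            expression, "Early", fpkm_threshold=thr, min_reads=cfg.min_reads
        )
        seqs = clustering_mod.activity_label_sequences(annotation, calls)
        res = clustering_mod.runs_test(seqs)
        rows.append(
            {
                "fpkm_threshold": thr,
                "n_runs": res.n_runs,
                "n_active": res.n_active,
                "n_inactive": res.n_inactive,
                "expected_runs": res.expected_runs,
                "z": res.z,
                "p": res.p,
                "mean_active_cluster_size": res.mean_active_cluster_size,
            }
        )
    io_mod.write_table(pd.DataFrame(rows), cfg.outdir / "runs_test.tsv")
    return {"runs_tests": len(rows)}


def _stage_landscape(cfg: PipelineConfig) -> dict[str, int]:
    annotation, expression = _load_inputs(cfg)
    p = _paths(cfg)
    rmap = io_mod.read_recombination_map(p["recomb_map"])
    calls = _calls_frame(expression, annotation, cfg.fpkm_strict, cfg.min_reads)
    windows = landscape_mod.bin_genome(annotation, cfg.window_size)
    metrics = landscape_mod.window_metrics(annotation, calls, windows)
    joined = landscape_mod.align_windows(metrics, rmap, include_partial=True)
    io_mod.write_table(
        joined.rename(columns={"rate": "cM_per_Mb"}), cfg.outdir / "window_metrics.tsv"
    )
    corr = landscape_mod.correlate_with_recombination(metrics, rmap)
    io_mod.write_table(corr, cfg.outdir / "landscape_correlations.tsv")
    reg = landscape_mod.multiple_regression(metrics, rmap)
    io_mod.write_table(reg, cfg.outdir / "landscape_regression.tsv")
    u, pval = landscape_mod.zero_vs_nonzero_transcription(metrics, rmap)
    io_mod.write_table(
        pd.DataFrame([{"U": u, "p": pval}]), cfg.outdir / "zero_vs_nonzero.tsv"
    )
    return {"windows": len(metrics), "correlations": len(corr)}


def _stage_dsb(cfg: PipelineConfig) -> dict[str, int]:
    annotation, expression = _load_inputs(cfg)
    p = _paths(cfg)
    events = io_mod.read_dsb_bed(p["dsbs"])
    events.validate_bounds(annotation)
    partition = dsb_mod.build_partition(
        annotation,
        expression.condition_mean_fpkm("Early"),
        silent_threshold=cfg.silent_threshold,
    )
    _, observed = dsb_mod.classify_events(events, partition)
    null = dsb_mod.monte_carlo_null(
        len(events), partition, n_replicates=cfg.n_replicates, seed=cfg.seed
    )
    results = dsb_mod.enrichment_test(observed, null, seed=cfg.seed)
    footprints = partition.footprints()
    out = pd.DataFrame(
        [
            {
                "category": r.category,
                "footprint_bp": footprints[r.category],
                "observed": r.observed,
                "expected": r.expected,
                "relative_presence": r.relative_presence,
                "p_empirical": r.p_empirical,
                "n_replicates": r.n_replicates,
                "seed": r.seed,
            }
            for r in results
        ]
    )
    io_mod.write_table(out, cfg.outdir / "dsb_enrichment.tsv")
    return {"dsbs": len(events), "categories": len(out)}


def _stage_poe(cfg: PipelineConfig) -> dict[str, int]:
    annotation, expression = _load_inputs(cfg)
    p = _paths(cfg)
    replicates = pd.read_csv(p["truth_replicates"], sep="\t")
    crosses = poe_mod.build_reciprocal_cross_set(expression, replicates)
    res = poe_mod.maternal_like_genes(crosses, q_threshold=cfg.q_threshold)
    rows = [
        {"maternal_strain": strain, "gene_id": g}
        for strain, genes in res.maternal_like.items()
        for g in genes
    ]
    io_mod.write_table(
        pd.DataFrame(rows, columns=["maternal_strain", "gene_id"]),
        cfg.outdir / "maternal_like_genes.tsv",
    )

    haps = io_mod.read_fasta(cfg.outdir / "haplotypes.fasta")
    hap_a, hap_b = haps["RAL-208"], haps["RAL-375"]
    reads = pd.read_csv(p["reads"], sep="\t")
    counts = poe_mod.count_alleles(reads, hap_a, hap_b)
    io_mod.write_table(counts.reset_index(), cfg.outdir / "allele_counts.tsv")
    try:
        ratio_res = poe_mod.allelic_ratio_test(counts, min_reads=cfg.min_allele_reads)
        summary = pd.DataFrame(
            [
                {
                    "n_genes": ratio_res.n_genes,
                    "n_above_half": ratio_res.n_above,
                    "n_below_half": ratio_res.n_below,
                    "excess_p": ratio_res.excess_p,
                }
            ]
        )
    except ValidationError:
        summary = pd.DataFrame(
            [{"n_genes": 0, "n_above_half": 0, "n_below_half": 0, "excess_p": float("nan")}]
        )
    io_mod.write_table(summary, cfg.outdir / "allelic_ratio_tests.tsv")
    return {
        "maternal_like": len(rows),
        "genes_with_ratio": int(counts["ratio"].notna().sum()),
    }


def _stage_novel(cfg: PipelineConfig) -> dict[str, int]:
    p = _paths(cfg)
    df = pd.read_csv(p["novel_candidates"], sep="\t")
    fpkm_cols = [c for c in df.columns if c.startswith("fpkm_s")]
    candidates = [
        novel_mod.NovelCandidate(
            id=row["id"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            fpkm=tuple(float(row[c]) for c in fpkm_cols),
            repetitive_fraction=float(row["repetitive_fraction"]),
            splice_junction_support=bool(row["splice_junction_support"]),
        )
        for _, row in df.iterrows()
    ]
    result = novel_mod.filter_cascade(candidates)
    counts = pd.DataFrame(
        [{"stage": s, "survivors": n} for s, n in result.counts.items()]
    )
    io_mod.write_table(counts, cfg.outdir / "novel_filter_counts.tsv")
    final = result.survivors[novel_mod.STAGES[-1]]
    bed = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.id) for c in final],
        columns=["chrom", "start", "end", "id"],
    )
    bed.to_csv(cfg.outdir / "novel_survivors.bed", sep="\t", index=False, header=False)
    return dict(result.counts)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "expression": _stage_expression,
    "clustering": _stage_clustering,
    "landscape": _stage_landscape,
    "dsb": _stage_dsb,
    "poe": _stage_poe,
    "novel": _stage_novel,
}


def run(subcommand: str, config: PipelineConfig) -> dict:
    """Run one stage (or ``"all"``) and update the run manifest.

    Returns the manifest dict.  Outputs are deterministic under a fixed
    seed; the manifest records version, seed, config hash and per-stage row
    counts.
    """
    if subcommand != "all" and subcommand not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {subcommand!r}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if subcommand == "all" else [subcommand]
    manifest_path = config.outdir / "manifest.json"
    manifest = {
        "package": "meiolandscape",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "stages": {},
    }
    if manifest_path.exists():
        try:
            prev = json.loads(manifest_path.read_text())
            if prev.get("config_sha256") == manifest["config_sha256"]:
                manifest["stages"] = prev.get("stages", {})
        except (json.JSONDecodeError, OSError):
            pass
    for stage in stages:
        logger.info("running stage %s", stage)
        manifest["stages"][stage] = _STAGE_FUNCS[stage](config)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
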