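import numpy as np
import pandas as pd
import pytest

from meiolandscape.simulate import (
    SimulationConfig,
    generate_expression,
    generate_genome,
)
from meiolandscape.types import Chromosome, ExpressionTable, Gene, GenomeAnnotation, SampleMeta


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Two chromosomes, five hand-placed genes, known coordinates."""
    return GenomeAnnotation(
        chromosomes=[
            Chromosome("chr2L", 10_000, "autosome"),
            Chromosome("chrX", 8_000, "X"),
        ],
        genes=[
            Gene("g1", "chr2L", 100, 600, "+", 400),
            Gene("g2", "chr2L", 400, 900, "-", 300),
            Gene("g3", "chr2L", 2_000, 2_500, "+", 500),
            Gene("g4", "chrX", 500, 1_500, "+", 800),
            Gene("g5", "chrX", 3_000, 3_600, "-", 600),
        ],
    )


def make_expression(
    gene_ids, fpkm_by_sample, reads_by_sample=None, conditions=None
) -> ExpressionTable:
    """Build a small ExpressionTable from dicts of per-sample vectors."""
    samples = []
    for sid in fpkm_by_sample:
        condition = (conditions or {}).get(sid, "Early" if "Early" in sid else "Late")
        samples.append(
            SampleMeta(
                sample_id=sid,
                condition=condition,
                genotype=sid.split("_")[0],
                gross_reads=1_000_000,
                mapped_reads=800_000,
            )
        )
    index = pd.Index(gene_ids, name="gene_id")
    fpkm = pd.DataFrame(fpkm_by_sample, index=index, dtype=float)
    if reads_by_sample is None:
        reads_by_sample = {
            sid: np.full(len(gene_ids), 100) for sid in fpkm_by_sample
        }
    reads = pd.DataFrame(reads_by_sample, index=index)
    return ExpressionTable(samples=samples, fpkm=fpkm, reads=reads)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_genes=300,
        chrom_lengths={"chr2L": 2_000_000, "chrX": 1_500_000},
        n_dsbs=500,
        n_reads=2_000,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """One modest synthetic genome + expression table, shared across tests."""
    annotation = generate_genome(small_config)
    expression, truth = generate_expression(annotation, small_config)
    return annotation, expression, truth
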