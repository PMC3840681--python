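"""Shared run configuration for the numbered analysis drivers.

One synthetic study at the published scale: 5,610 DSB events tested against
10,000 random-placement replicates over 100-kb windows, eight libraries
(4 genotypes × Early/Late), 100-read allele floor.  Every driver reads and
writes under results/pipeline so the stages compose like the original
workflow; rerunning with the same seed reproduces every table byte for byte.
"""

from pathlib import Path

from meiolandscape.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def pipeline_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(outdir=RESULTS, seed=seed)
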