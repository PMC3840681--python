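"""Generate the synthetic study inputs.

Writes the genome annotation (GFF3), the eight-sample expression table, the
100-kb recombination map with its planted transcription dependence, 5,610
DSB events, parental haplotypes with reads of known origin, novel-transcript
candidates, and the planted-truth tables that later drivers score against.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, pipeline_config

from meiolandscape.pipeline import run


def main() -> None:
    manifest = run("simulate", pipeline_config())
    counts = manifest["stages"]["simulate"]
    print(f"wrote inputs under {RESULTS}")
    print(
        f"  {counts['genes']} genes, {counts['samples']} samples, "
        f"{counts['windows']} windows, {counts['dsbs']} DSBs, "
        f"{counts['reads']} reads, {counts['novel_candidates']} novel candidates"
    )


if __name__ == "__main__":
    main()
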