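"""Are transcribed genes randomly ordered along chromosomes?

Runs the Wald-Wolfowitz runs test on the ordered activity labels at both
FPKM thresholds; the planted Markov clustering should show up as fewer runs
than expected (z < 0) with sizeable mean cluster sizes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, pipeline_config

from meiolandscape.pipeline import run


def main() -> None:
    run("clustering", pipeline_config())
    table = pd.read_csv(RESULTS / "runs_test.tsv", sep="\t")
    print(table.to_string(index=False))
    for _, row in table.iterrows():
        verdict = "clustered" if row["p"] < 0.05 and row["z"] < 0 else "unstructured"
        print(
            f"FPKM > {row['fpkm_threshold']}: {row['n_runs']} runs vs "
            f"{row['expected_runs']:.1f} expected (z = {row['z']:.2f}, "
            f"p = {row['p']:.2g}) -> {verdict}; mean active cluster "
            f"{row['mean_active_cluster_size']:.2f} genes"
        )


if __name__ == "__main__":
    main()
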