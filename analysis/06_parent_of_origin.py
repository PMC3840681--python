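"""Parent-of-origin effects and allele-specific expression.

Classifies maternal-like genes from the reciprocal crosses (significant
offspring difference in the direction of the maternal strains' difference),
scores the recovery of the generator's planted effects, and summarizes
allele-specific read assignment under the zero-mismatch / 100-read rules.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, pipeline_config

from meiolandscape.pipeline import run


def main() -> None:
    run("poe", pipeline_config())
    maternal = pd.read_csv(RESULTS / "maternal_like_genes.tsv", sep="\t")
    truth = pd.read_csv(RESULTS / "truth_genes.tsv", sep="\t").set_index("gene_id")
    counts = pd.read_csv(RESULTS / "allele_counts.tsv", sep="\t")
    ratio = pd.read_csv(RESULTS / "allelic_ratio_tests.tsv", sep="\t")

    found = set(maternal["gene_id"])
    planted = set(truth.index[truth["maternal_flag"]])
    per_strain = maternal["maternal_strain"].value_counts().to_dict()
    print(
        f"maternal-like genes: {len(found)} "
        f"({per_strain}) of {len(planted)} planted; "
        f"recovered {len(found & planted)}, spurious {len(found - planted)}"
    )
    with_ratio = counts[counts["ratio"].notna()]
    print(
        f"\nallele-specific reads: {int(counts['reads_A'].sum())} A / "
        f"{int(counts['reads_B'].sum())} B assigned, "
        f"{int(counts['ambiguous'].sum())} ambiguous, "
        f"{int(counts['excluded_N'].sum())} N-excluded; "
        f"{len(with_ratio)} genes pass the 100-read floor"
    )
    row = ratio.iloc[0]
    print(
        f"genome-wide allele excess (sign test vs 0.5): "
        f"{int(row['n_above_half'])} above / {int(row['n_below_half'])} below, "
        f"p = {row['excess_p']:.3g}"
    )


if __name__ == "__main__":
    main()
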