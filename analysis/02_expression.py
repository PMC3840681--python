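"""Expression landscape: mapping rates, fold changes, and the X-chromosome excess.

Reports the per-sample percent-mapped summary, the most extreme Early-vs-Late
fold changes (signed: negative = lower in Early), and the proportion of
transcribed genes on the X versus the autosomes with its chi-square test.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, pipeline_config

from meiolandscape.pipeline import run


def main() -> None:
    run("expression", pipeline_config())
    mapping = pd.read_csv(RESULTS / "mapping_summary.tsv", sep="\t")
    fc = pd.read_csv(RESULTS / "fold_changes.tsv", sep="\t")
    contrast = pd.read_csv(RESULTS / "x_vs_autosome.tsv", sep="\t")

    print("percent mapped per sample:")
    print(mapping.to_string(index=False))
    print("\nmost extreme fold changes (top 5 either direction):")
    print(fc.head(5).to_string(index=False))
    print(fc.tail(5).to_string(index=False))
    print("\nX vs autosome transcribed-gene proportions:")
    print(contrast.to_string(index=False))
    early_strict = contrast.query("condition == 'Early' and fpkm_threshold == 1.0")
    row = early_strict.iloc[0]
    print(
        f"\nEarly, FPKM > 1: {100 * row['proportion_X']:.1f}% of X genes vs "
        f"{100 * row['proportion_autosome']:.1f}% of autosomal genes transcribed "
        f"(chi2 = {row['chi2']:.1f}, p = {row['p']:.2g})"
    )


if __name__ == "__main__":
    main()
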