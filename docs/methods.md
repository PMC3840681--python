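# Methods

## Scope and data model

The package re-creates the downstream analyses of an early-meiosis ovarian
mRNA-seq study as a tested pipeline over standard formats: GFF3/BED12 gene
annotations, long-TSV expression tables (gene × sample FPKM and mapped-read
counts), BED-like recombination maps of fixed 100-kb windows in cM/Mb, BED3
DSB intervals (≤ 500 bp), and FASTA parental haplotypes with reads. All
internal coordinates are 0-based half-open; GFF3 converts at the I/O
boundary. Strand is carried but ignored — the window, clustering and DSB
analyses are strand-agnostic. Expression cells can be *absent* (NaN), which
is distinct from zero: threshold operations treat absent as not expressed
and report the count. Upstream read grooming, alignment, transcript
assembly and dispersion-model differential-expression testing are out of
scope; the pipeline consumes FPKM tables and, where needed, per-gene
p-values.

## Activity calling and expression summaries

A gene is actively expressed in a condition when every sample of that
condition has ≥ 10 mapped reads and FPKM strictly above the threshold
(0.1 permissive, 1 for the windowed landscape). The signed fold change
between conditions is +a/b when a ≥ b and −b/a otherwise, so its magnitude
is always ≥ 1; genes with zero FPKM in either condition are excluded from
fold-change rankings rather than pseudocounted (the number excluded is
reported). Multiple testing uses Benjamini–Hochberg step-up q-values
(statsmodels), cross-checked in the tests against a literal step-up oracle.
The X-vs-autosome contrast is a 2×2 Pearson chi-square without continuity
correction (flag to enable Yates); unplaced scaffolds are excluded. Paired
Early/Late level comparisons use the Wilcoxon signed-rank test with normal
approximation and tie correction, re-signed so z > 0 means the first sample
ranks higher; below 10 pairs a warning flags the approximation.

## Runs test and cluster sizes

Genes are ordered by (chromosome, start, end, id); overlapping genes each
contribute one label. Runs are counted within chromosomes and the
Wald–Wolfowitz moments (E[R] = 2n₁n₂/n + 1,
Var[R] = 2n₁n₂(2n₁n₂ − n)/(n²(n − 1))) are summed across chromosomes, so
chromosome ends never fabricate label switches; a genome-as-one-sequence
mode exists for comparison. The p-value is two-sided; clustering manifests
as z < 0. Mean cluster size is the mean length of maximal active runs,
pooled across chromosomes. Single-label sequences return run counts with
z/p undefined and an explanatory note.

## Windowed landscape

Windows are adjacent, left-closed, 100 kb by default; the final partial
window is kept but flagged and excluded from correlations by default (its
per-Mb normalization differs). Gene counting and OTA use the midpoint rule
(a gene contributes to exactly one window) to avoid double-counting FPKM
mass; kb_transcribed instead clips the union of genomic footprints to each
window, counting overlaps once. OTA uses the exonic transcript length,
kb_transcribed the genomic footprint. OTA is undefined (NaN) in windows
with no transcribed base — not −∞; correlations drop undefined windows per
metric, while the joint OLS imputes minimum-observed-OTA − 1 and reports
how many windows were imputed. The regression is ordinary least squares on
raw variables with intercept (a rank-transform flag is provided since rank
regression is an equally defensible choice); a constant response returns
zero slopes with p = 1, and degenerate zero-residual fits report p = 1
rather than machine-precision artifacts. The regression refuses fewer than
`min_windows` (default 10) windows.

## DSB enrichment

Genes with FPKM < 0.001 are silent; active genes are ranked by
FPKM × transcript length and split at count tertiles into low/medium/high
(configurable cuts; exactly two cuts, i.e. three groups). The published
33/46/21% group proportions imply cut values never stated; the tertile
default intentionally does not reproduce them. At a base covered by genes
of different categories the higher category wins (contested bases are
counted); uncovered sequence is intergenic, and the category footprints
always partition the genome. Observed events and null placements are both
reduced to midpoints, keeping the two commensurable for ≤ 500-bp intervals.
Each of the 10,000 null replicates places n event midpoints uniformly over
the concatenated genome; the empirical p doubles the smaller tail count
with an add-one correction — min(1, (1 + 2·min tail)/(1 + R)) — so it is
two-sided, never zero, and floors at 1/(R + 1).

## Parent-of-origin analysis

A maternal-like gene shows a significant reciprocal-cross offspring
difference whose sign matches the parental strains' difference; the set is
split by which maternal strain expresses higher (the strain whose level the
elevated cross tracks). Significant genes shifting against the parental
direction are reported as discordant — they are parent-of-origin effects
but not maternal-like — and genes with zero parental difference as
unresolved. Significance is consumed from upstream; for synthetic data a
per-gene Welch t-test on log FPKM across simulated replicate libraries
stands in for a dispersion-modelling DE step. It runs slightly
conservative at three libraries per group, which the calibration tests
account for.

Allele-specific assignment replaces full re-mapping with a locus-anchored
exact comparison: a read is assigned to the parent it matches with zero
mismatches when it does not match the other; matches to both (no
informative SNP) or to neither are unassignable, and a read over a span
where either haplotype carries an N is excluded outright. Ratios
(reads_A/(reads_A+reads_B)) require ≥ 100 assigned reads per gene. The
genome-wide allele excess is a two-sided exact binomial (sign) test of
per-gene ratios against 0.5 (ratios exactly 0.5 are uninformative); the
cross-to-cross shift is the Wilcoxon matched-pairs test on per-gene ratios.

## Novel-transcript filter

The cascade applies, in fixed order: detected (FPKM > 0) in ≥ 2 samples;
FPKM > 1 in ≥ 1 sample; length > 300 bp with repetitive fraction ≤ 0.5 and
splice-junction support. Repeat fractions and junction support arrive as
candidate attributes (assembler territory, applied by inspection in
practice); the final visual-curation step is out of algorithmic scope. The
cascade is monotone by construction and per-stage survivor counts are
reported; stage order is fixed and order-invariance is not claimed.

## Synthetic-data generator

The generator defines the study conditions; all randomness flows from one
seed through independent per-stage generator streams, so a fixed seed is
bit-reproducible.

* **Genome** — default 14 Mb across chr2L/chr2R (5 Mb each) and chrX
  (4 Mb) with 1,500 non-overlapping genes: lognormal footprints (ln-mean
  7.9, ln-sd 0.6; median ≈ 2.7 kb), uniformly broken intergenic gaps, and
  an exonic fraction of 0.5–0.95 giving the transcript length. This keeps
  the fly-like gene density (~1 gene / 9 kb) at desk scale.
* **Expression** — eight samples (4 genotypes × Early/Late, two parental
  strains and their reciprocal crosses), each the mean of 3 simulated
  libraries with log-noise sd 0.15. Activity states follow a two-state
  Markov chain along gene order with persistence 0.6 (the simplest
  mechanism producing physical clustering; mean run ≈ 3 genes at the
  strict threshold) and marginal activity 0.62 on the X vs 0.55 on
  autosomes, reproducing the X excess qualitatively. Active genes draw
  lognormal FPKM (ln-mean 2, ln-sd 1.5); per-gene condition and strain
  effects are Gaussian (sd 0.4 and 0.3 in logs). A fraction 0.1 of active
  genes carries a planted maternal effect: a ±1.5-log parental gap with
  offspring pulled toward the maternal parent by weight 0.9. Mapped reads
  per gene are Poisson with mean FPKM × kb × 5 (a 5M-read library scale),
  so the 10-read floor interacts with thresholds as in real data.
* **Recombination map** — per 100-kb window,
  rate = max(0, 2 + 0.15·n_transcribed + 0.02·kb + 0·OTA + trend + noise)
  cM/Mb, with a bell-shaped chromosomal trend (amplitude 1.5·sin(πx/L))
  and Gaussian noise sd 0.8. The defaults plant the gene-count and length
  dependence and no independent OTA effect, mirroring which predictors the
  joint regression should find relevant.
* **DSBs** — 5,610 events drawn category-first with probability
  ∝ weight × footprint (equal weights by default, i.e. a uniform genome),
  midpoint uniform within the category footprint, width uniform in
  50–500 bp clipped to the chromosome. True categories are emitted.
* **Haplotypes/reads** — a 60-kb pair of parental sequences differing by
  SNPs at 0.005/bp (DGRP-like strain divergence) with Ns at 0.001/bp in
  one parent, and 10,000 error-free 120-bp reads drawn from the parents at
  a configurable ratio with true origins recorded. Reads are error-free by
  design: under the zero-mismatch rule, sequencing error only deletes
  reads and would confound the assignment guarantees being tested.
* **Novel candidates** — 200 intervals with independently drawn detection
  breadth, peak FPKM, length, repeat fraction and junction support, so the
  cascade's survivor counts are known by construction.

What the generator does *not* emulate: isoform structure, fragment-level
FPKM estimation, sequencing error, GC or mappability biases, linkage
between expression level and gene length, and real recombination-map error
structure. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the planted model, not that
real data would show these effects.

## Calibration and recovery checks

The acceptance-level tests run at the study's stated sizes: 5,610 uniform
events against 10,000 replicates (every relative presence within
0.9–1.1 and null means within 3 binomial SEs of the analytic footprint
expectation); 2× placement weight on transcribed genes recovered with
empirical p ≤ 0.001; the planted window–transcription association detected
(ρ > 0, p < 0.05) in ≥ 95/100 seeds at ~1,000 windows, with null-beta
rejection at 5% ± 2 over 1,000 reduced-size genomes (two 2-Mb chromosomes,
400 genes — small enough to regenerate a thousand times, large enough for
the Spearman approximation); runs-test type-I error 5% ± 2 over 1,000
unclustered label sets; zero misassigned reads among 10,000 and a planted
0.6 allelic ratio recovered within 3 binomial SDs; kb_transcribed and the
chi-square equal per-base-scan and Σ(O−E)²/E oracles on 1,000 fuzzed
instances.

## Numerical and degenerate-input choices

Empirical p-values are never zero (add-one rule). Tertile splits use
stable argsort so ties break deterministically by gene order. The runs
test returns notes instead of z/p when a label class is missing.
`percent_mapped` refuses zero gross reads. Identical paired vectors give
(z, p) = (0, 1) rather than an error. Fold change at equal inputs is +1 in
both directions (the one point where antisymmetry intentionally fails).
Window tiling always conserves total chromosome length. The known
discrepancy that a median mapped-read count computed from the published
per-sample table differs from the published median is noted and left
unresolved; nothing downstream uses it.
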