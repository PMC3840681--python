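"""Transcription-category partition and Monte-Carlo DSB enrichment."""

import numpy as np
import pandas as pd
import pytest

from meiolandscape import dsb as D
from meiolandscape.types import (
    Chromosome,
    DSBEventSet,
    Gene,
    GenomeAnnotation,
    ValidationError,
)


def annotation(genes, length=100_000):
    return GenomeAnnotation(
        chromosomes=[Chromosome("chr2L", length, "autosome")], genes=genes
    )


def fpkm_series(values):
    return pd.Series(values, name="fpkm")


class TestBuildPartition:
    def test_no_genes_is_all_intergenic(self):
        part = D.build_partition(annotation([]), fpkm_series({}))
        fp = part.footprints()
        assert fp["intergenic"] == 100_000
        assert sum(fp.values()) == part.genome_length

    def test_all_silent_genes(self):
        genes = [Gene("g1", "chr2L", 0, 1_000, "+", 1_000)]
        part = D.build_partition(annotation(genes), fpkm_series({"g1": 0.0}))
        fp = part.footprints()
        assert fp["silent"] == 1_000
        assert fp["low"] == fp["medium"] == fp["high"] == 0

    def test_nine_active_genes_split_three_ways(self):
        genes = [
            Gene(f"g{i}", "chr2L", i * 2_000, i * 2_000 + 1_000, "+", 1_000)
            for i in range(9)
        ]
        fpkm = fpkm_series({f"g{i}": float(i + 1) for i in range(9)})
        part = D.build_partition(annotation(genes), fpkm)
        counts = part.gene_category.value_counts()
        assert counts["low"] == counts["medium"] == counts["high"] == 3

    def test_footprints_partition_the_genome(self, small_world):
        ann, expr, _ = small_world
        part = D.build_partition(ann, expr.condition_mean_fpkm("Early"))
        assert sum(part.footprints().values()) == part.genome_length

    def test_overlapping_genes_higher_category_wins(self):
        genes = [
            Gene("lo", "chr2L", 0, 2_000, "+", 2_000),
            Gene("hi", "chr2L", 1_000, 3_000, "+", 2_000),
        ]
        # both active; "hi" has the larger FPKM x length score, so with two
        # genes the count tertiles put "lo" in the bottom and "hi" in the
        # top group
        part = D.build_partition(
            annotation(genes), fpkm_series({"lo": 1.0, "hi": 100.0})
        )
        assert part.gene_category["hi"] == "high"
        assert part.category_at("chr2L", 1_500) == "high"
        assert part.n_contested_bases == 1_000

    def test_bad_cuts_rejected(self):
        with pytest.raises(ValidationError):
            D.build_partition(
                annotation([]), fpkm_series({}), activity_cuts=(0.8, 0.2)
            )


class TestClassifyEvents:
    def _part(self):
        genes = [
            Gene("silent1", "chr2L", 10_000, 12_000, "+", 2_000),
            Gene("active1", "chr2L", 50_000, 52_000, "+", 2_000),
        ]
        return D.build_partition(
            annotation(genes), fpkm_series({"silent1": 0.0, "active1": 5.0})
        )

    def test_midpoint_rules(self):
        part = self._part()
        events = DSBEventSet(
            events=pd.DataFrame(
                {
                    "chrom": ["chr2L"] * 3,
                    "start": [10_500, 30_000, 11_900],
                    "end": [10_700, 30_400, 12_300],
                }
            )
        )
        cats, counts = D.classify_events(events, part)
        assert cats.tolist()[0] == "silent"
        assert cats.tolist()[1] == "intergenic"
        # straddles the gene edge but its midpoint (12_100) lies outside
        assert cats.tolist()[2] == "intergenic"
        assert sum(counts.values()) == 3

    def test_out_of_bounds_event_named(self):
        part = self._part()
        events = DSBEventSet(
            events=pd.DataFrame(
                {"chrom": ["chr2L"], "start": [99_900], "end": [100_300]}
            )
        )
        with pytest.raises(ValidationError, match="outside"):
            D.classify_events(events, part)


class TestMonteCarloNull:
    def test_single_category_gets_everything(self):
        part = D.build_partition(annotation([]), fpkm_series({}))
        null = D.monte_carlo_null(1_000, part, n_replicates=200, seed=1)
        assert (null["intergenic"] == 1_000).all()
        assert (null[["silent", "low", "medium", "high"]] == 0).all().all()

    def test_fixed_seed_reproducible(self):
        genes = [Gene("g1", "chr2L", 0, 25_000, "+", 25_000)]
        part = D.build_partition(annotation(genes), fpkm_series({"g1": 2.0}))
        a = D.monte_carlo_null(500, part, n_replicates=300, seed=42)
        b = D.monte_carlo_null(500, part, n_replicates=300, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_counts_conserved_per_replicate(self):
        genes = [Gene("g1", "chr2L", 0, 25_000, "+", 25_000)]
        part = D.build_partition(annotation(genes), fpkm_series({"g1": 2.0}))
        null = D.monte_carlo_null(777, part, n_replicates=300, seed=0)
        assert (null.sum(axis=1) == 777).all()

    def test_expected_matches_binomial_oracle(self):
        # one active gene covering exactly 25% of the genome
        genes = [Gene("g1", "chr2L", 0, 25_000, "+", 25_000)]
        part = D.build_partition(annotation(genes), fpkm_series({"g1": 2.0}))
        null = D.monte_carlo_null(1_000, part, n_replicates=10_000, seed=5)
        cat = part.gene_category["g1"]
        binom_sd = np.sqrt(1_000 * 0.25 * 0.75)
        # per-replicate counts behave like Binomial(n, 0.25)
        assert abs(null[cat].std(ddof=1) - binom_sd) < 0.1 * binom_sd
        # and the null mean sits within Monte-Carlo error of the analytic value
        assert abs(null[cat].mean() - 250.0) < 3 * binom_sd / np.sqrt(10_000)


class TestEnrichmentTest:
    def _null(self):
        rng = np.random.default_rng(0)
        counts = rng.binomial(1_000, 0.25, size=(2_000, 1))
        frame = pd.DataFrame(
            {
                "intergenic": 1_000 - counts[:, 0],
                "silent": 0,
                "low": counts[:, 0],
                "medium": 0,
                "high": 0,
            }
        )
        return frame

    def test_central_observation_has_large_p(self):
        null = self._null()
        obs = {"intergenic": 750, "silent": 0, "low": 250, "medium": 0, "high": 0}
        results = {r.category: r for r in D.enrichment_test(obs, null)}
        assert results["low"].p_empirical > 0.5
        assert results["low"].relative_presence == pytest.approx(1.0, abs=0.05)

    def test_extreme_observation_hits_the_floor(self):
        null = self._null()
        obs = {"intergenic": 400, "silent": 0, "low": 600, "medium": 0, "high": 0}
        results = {r.category: r for r in D.enrichment_test(obs, null)}
        assert results["low"].p_empirical == pytest.approx(1 / 2_001)

    def test_p_is_never_zero(self):
        null = self._null()
        for obs_low in (0, 250, 1_000):
            obs = {"intergenic": 1_000 - obs_low, "low": obs_low}
            for r in D.enrichment_test(obs, null):
                assert r.p_empirical > 0.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValidationError):
            D.enrichment_test({"low": 1}, self._null().head(50))
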