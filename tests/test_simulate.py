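"""Synthetic-data generators: determinism, invariants, and planted-effect calibration."""

import numpy as np
import pandas as pd
import pytest

from meiolandscape import dsb as D
from meiolandscape import parent_of_origin as P
from meiolandscape.clustering import activity_label_sequences, runs_test
from meiolandscape.expression import call_active_table, chromosome_activity_contrast
from meiolandscape.simulate import (
    SimulationConfig,
    generate_dsbs,
    generate_expression,
    generate_genome,
    generate_haplotypes_and_reads,
    generate_novel_candidates,
    generate_recombination_map,
)
from meiolandscape.types import ValidationError


def small_cfg(**kw):
    base = dict(
        seed=11,
        n_genes=300,
        chrom_lengths={"chr2L": 2_000_000, "chrX": 1_500_000},
        n_dsbs=500,
        n_reads=2_000,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenome:
    def test_empty_gene_list(self):
        ann = generate_genome(small_cfg(n_genes=0))
        assert ann.genes == []

    def test_fixed_seed_reproducible(self):
        a = generate_genome(small_cfg())
        b = generate_genome(small_cfg())
        assert a.genes == b.genes and a.chromosomes == b.chromosomes

    def test_invariants_hold_at_scale(self):
        cfg = SimulationConfig(
            seed=3, n_genes=1_000, chrom_lengths={"chr2L": 10_000_000, "chrX": 10_000_000}
        )
        ann = generate_genome(cfg)
        assert len(ann.genes) == 1_000
        for chrom in ann.chrom_names:
            genes = ann.genes_on(chrom)
            length = ann.chromosome(chrom).length
            for g in genes:
                assert 0 <= g.start < g.end <= length
                assert g.transcript_length > 0
            for prev, cur in zip(genes, genes[1:]):
                assert prev.end <= cur.start  # non-overlapping
        assert any(c.chrom_class == "X" for c in ann.chromosomes)

    def test_overfull_chromosome_rejected(self):
        with pytest.raises(ValidationError, match="footprint"):
            generate_genome(
                SimulationConfig(seed=0, n_genes=500, chrom_lengths={"chr2L": 100_000})
            )


class TestExpression:
    def test_fixed_seed_reproducible(self, small_config, small_world):
        ann, expr, _ = small_world
        expr2, _ = generate_expression(ann, small_config)
        assert expr2 == expr

    def test_eight_samples_mirroring_design(self, small_world):
        _, expr, _ = small_world
        assert len(expr.samples) == 8
        assert {s.condition for s in expr.samples} == {"Early", "Late"}
        assert len({s.genotype for s in expr.samples}) == 4
        maternal = {s.genotype: s.maternal_strain for s in expr.samples}
        assert maternal["375Fx208M"] == "RAL-375"
        assert maternal["208Fx375M"] == "RAL-208"
        for s in expr.samples:
            assert s.mapped_reads <= s.gross_reads

    def test_inactive_genes_have_zero_fpkm(self, small_world):
        _, expr, truth = small_world
        inactive = truth.genes.index[~truth.genes["active"]]
        assert (expr.fpkm.loc[inactive] == 0).all().all()
        assert (expr.reads.loc[inactive] == 0).all().all()

    def test_zero_clustering_gives_calibrated_runs_test(self):
        """With no planted clustering the runs test rejects at ~alpha."""
        rejections = 0
        for seed in range(100):
            cfg = small_cfg(seed=seed, clustering_strength=0.0, n_genes=400)
            ann = generate_genome(cfg)
            expr, _ = generate_expression(ann, cfg)
            calls = call_active_table(expr, "Early", fpkm_threshold=1.0)
            res = runs_test(activity_label_sequences(ann, calls))
            rejections += res.p is not None and res.p < 0.05
        assert rejections <= 6  # non-significant in >= 94% of seeds

    def test_clustered_generator_is_detected(self, small_world):
        ann, expr, _ = small_world  # default clustering_strength = 0.6
        calls = call_active_table(expr, "Early", fpkm_threshold=1.0)
        res = runs_test(activity_label_sequences(ann, calls))
        assert res.z < 0 and res.p < 1e-4

    def test_equal_x_activity_gives_calibrated_chi2(self):
        # clustering must be off: the chi-square assumes independent genes,
        # and correlated activity labels genuinely inflate it
        rejections = 0
        for seed in range(60):
            cfg = small_cfg(
                seed=seed, p_active_x=0.55, n_genes=400, clustering_strength=0.0
            )
            ann = generate_genome(cfg)
            expr, _ = generate_expression(ann, cfg)
            calls = call_active_table(expr, "Early", fpkm_threshold=1.0)
            rejections += chromosome_activity_contrast(calls, ann).p < 0.05
        # ~alpha = 0.05 of 60 seeds, allow 3 binomial SDs
        assert rejections <= 0.05 * 60 + 3 * np.sqrt(60 * 0.05 * 0.95)

    def test_x_excess_emerges_with_planted_gap(self, small_world):
        ann, expr, _ = small_world  # p_active_x 0.62 vs 0.55
        calls = call_active_table(expr, "Early", fpkm_threshold=1.0)
        res = chromosome_activity_contrast(calls, ann)
        assert res.proportion_x > res.proportion_autosome

    def test_null_maternal_classifier_matches_false_positive_rate(self):
        from meiolandscape.parent_of_origin import (
            build_reciprocal_cross_set,
            maternal_like_genes,
        )

        found = expected = 0
        for seed in range(5):
            cfg = small_cfg(seed=seed, maternal_effect_fraction=0.0, n_genes=600)
            ann = generate_genome(cfg)
            expr, truth = generate_expression(ann, cfg)
            cr = build_reciprocal_cross_set(expr, truth.replicates)
            res = maternal_like_genes(cr, q_threshold=0.05, use_q=False)
            found += sum(len(v) for v in res.maternal_like.values())
            expected += 0.05 * truth.genes["active"].sum()
        # every maternal-like call here is a false positive; the simple
        # Welch test at 3 libraries runs slightly conservative
        assert 0.2 * expected <= found <= 1.5 * expected

    def test_planted_maternal_effects_recovered(self, small_config, small_world):
        from meiolandscape.parent_of_origin import (
            build_reciprocal_cross_set,
            maternal_like_genes,
        )

        ann, expr, truth = small_world
        cr = build_reciprocal_cross_set(expr, truth.replicates)
        res = maternal_like_genes(cr)
        found = {
            g for genes in res.maternal_like.values() for g in genes
        }
        planted = set(truth.genes.index[truth.genes["maternal_flag"]])
        assert len(found & planted) >= 0.4 * len(planted)
        assert len(found - planted) <= 0.1 * max(len(found), 1)
        # the strain split matches the planted high-expressing maternal strain
        high = truth.genes["maternal_high_strain"]
        for strain, genes in res.maternal_like.items():
            for g in genes:
                if g in planted:
                    assert high[g] == strain


class TestRecombinationMap:
    def test_zero_betas_zero_noise_equal_trend_plus_base(self, small_world):
        ann, expr, _ = small_world
        cfg = small_cfg(
            beta_genes=0.0, beta_kb=0.0, beta_ota=0.0, recomb_noise_sd=0.0
        )
        rmap = generate_recombination_map(ann, expr, cfg)
        w = rmap.windows
        centers = (w["start"] + w["end"]) / 2
        lengths = w["chrom"].map({c.name: c.length for c in ann.chromosomes})
        trend = cfg.recomb_trend_amplitude * np.sin(np.pi * centers / lengths)
        np.testing.assert_allclose(
            w["rate"], np.maximum(cfg.recomb_base_rate + trend, 0.0), atol=1e-12
        )

    def test_planted_gene_effect_recovered(self, small_world):
        from meiolandscape.expression import call_active_table
        from meiolandscape.landscape import (
            bin_genome,
            correlate_with_recombination,
            window_metrics,
        )

        ann, expr, _ = small_world
        cfg = small_cfg(beta_genes=0.5, recomb_trend_amplitude=0.0)
        rmap = generate_recombination_map(ann, expr, cfg)
        calls = pd.DataFrame(
            {
                "active": call_active_table(expr, "Early", fpkm_threshold=1.0),
                "fpkm": expr.condition_mean_fpkm("Early"),
            }
        )
        metrics = window_metrics(ann, calls, bin_genome(ann, cfg.window_size))
        corr = correlate_with_recombination(metrics, rmap)
        row = corr[corr["metric"] == "n_transcribed"].iloc[0]
        assert row["rho"] > 0 and row["p"] < 0.05

    def test_rates_never_negative(self, small_world):
        ann, expr, _ = small_world
        cfg = small_cfg(recomb_base_rate=0.0, recomb_noise_sd=3.0)
        rmap = generate_recombination_map(ann, expr, cfg)
        assert (rmap.windows["rate"] >= 0).all()


class TestDSBGenerator:
    def test_fixed_seed_reproducible(self, small_world):
        ann, expr, _ = small_world
        a = generate_dsbs(ann, expr, small_cfg())
        b = generate_dsbs(ann, expr, small_cfg())
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_zero_weight_category_gets_no_events(self, small_world):
        ann, expr, _ = small_world
        weights = {c: 1.0 for c in D.CATEGORIES}
        weights["intergenic"] = 0.0
        ev = generate_dsbs(ann, expr, small_cfg(dsb_category_weights=weights))
        assert (ev.events["category"] != "intergenic").all()

    def test_widths_and_bounds(self, small_world):
        ann, expr, _ = small_world
        ev = generate_dsbs(ann, expr, small_cfg())
        widths = ev.events["end"] - ev.events["start"]
        assert widths.between(1, 500).all()
        ev.validate_bounds(ann)

    def test_truth_labels_match_midpoint_classification(self, small_world):
        ann, expr, _ = small_world
        ev = generate_dsbs(ann, expr, small_cfg())
        part = D.build_partition(ann, expr.condition_mean_fpkm("Early"))
        cats, _ = D.classify_events(ev, part)
        assert (cats.to_numpy() == ev.events["category"].to_numpy()).all()


class TestHaplotypesAndReads:
    def test_fixed_seed_reproducible(self):
        a = generate_haplotypes_and_reads(small_cfg())
        b = generate_haplotypes_and_reads(small_cfg())
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_zero_snp_density_makes_every_read_ambiguous(self):
        cfg = small_cfg(snp_density=0.0, n_rate=0.0, n_reads=500)
        hap_a, hap_b, reads, _ = generate_haplotypes_and_reads(cfg)
        assert hap_a == hap_b
        counts = P.count_alleles(reads, hap_a, hap_b)
        assert counts["ambiguous"].sum() == 500
        assert (counts[["reads_A", "reads_B"]] == 0).all().all()

    def test_planted_even_ratio_recovered(self):
        cfg = small_cfg(n_reads=10_000)
        hap_a, hap_b, reads, _ = generate_haplotypes_and_reads(cfg)
        counts = P.count_alleles(reads, hap_a, hap_b)
        a, b = counts["reads_A"].sum(), counts["reads_B"].sum()
        n = a + b
        sd = np.sqrt(n * 0.25)
        assert abs(a - n / 2) <= 3 * sd

    def test_error_free_reads_never_misassigned(self):
        cfg = small_cfg(n_reads=2_000)
        hap_a, hap_b, reads, _ = generate_haplotypes_and_reads(cfg)
        counts = P.count_alleles(reads, hap_a, hap_b)
        merged = reads.assign(assigned=counts.attrs["assignments"])
        wrong = (
            ((merged["assigned"] == "A") & (merged["true_origin"] == "B"))
            | ((merged["assigned"] == "B") & (merged["true_origin"] == "A"))
        )
        assert int(wrong.sum()) == 0


class TestNovelCandidates:
    def test_reproducible_and_valid(self, small_world):
        ann, _, _ = small_world
        a = generate_novel_candidates(ann, small_cfg(), n_candidates=50)
        b = generate_novel_candidates(ann, small_cfg(), n_candidates=50)
        assert [c.id for c in a] == [c.id for c in b]
        assert all(0 <= c.start < c.end for c in a)
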